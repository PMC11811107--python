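"""Scatterplots of ordination scores and mean-shape wireframes."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Landmark connection order for the 7-landmark discal-cell wireframe.
WING_WIREFRAME = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 0)]


def _confidence_ellipse(ax, points: np.ndarray, level: float, **kwargs):
    """Draw an equal-frequency ellipse of the fitted bivariate normal."""
    from matplotlib.patches import Ellipse

    if len(points) < 3:
        return
    mean = points.mean(axis=0)
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    # chi-square quantile on 2 df sets the ellipse radius
    r2 = stats.chi2.ppf(level, df=2)
    width, height = 2 * np.sqrt(np.clip(evals, 0, None) * r2)
    angle = np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1]))
    ax.add_patch(
        Ellipse(mean, height, width, angle=angle, fill=False, **kwargs)
    )


def plot_scores(scores: np.ndarray, groups=None, ax=None, ellipse: float = 0.9,
                xlabel: str = "", ylabel: str = ""):
    """Scatter two score columns, coloured by group, with confidence ellipses.

    ``ellipse`` is the equal-frequency level (0 disables), default 90%.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    scores = np.asarray(scores)
    if groups is None:
        groups = np.array(["all"] * len(scores), dtype=object)
    groups = np.asarray(groups, dtype=object)
    for i, g in enumerate(sorted(set(groups))):
        pts = scores[groups == g]
        color = f"C{i % 10}"
        ax.scatter(pts[:, 0], pts[:, 1], s=18, label=str(g), color=color,
                   alpha=0.75)
        if ellipse and np.ptp(pts, axis=0).min() > 0:
            _confidence_ellipse(ax, pts, ellipse, edgecolor=color, lw=1.2)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    ax.figure.tight_layout()
    return ax


def plot_wireframe(shape: np.ndarray, ax=None, connections=None,
                   color: str = "C0", label: str | None = None):
    """Draw a landmark configuration as a wireframe with numbered landmarks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    shape = np.asarray(shape)
    if connections is None and shape.shape[0] == 7:
        connections = WING_WIREFRAME
    if connections:
        for i, j in connections:
            ax.plot(shape[[i, j], 0], shape[[i, j], 1], color=color, lw=1.2)
    ax.scatter(shape[:, 0], shape[:, 1], color=color, zorder=3, label=label)
    for idx, (x, y) in enumerate(shape, start=1):
        ax.annotate(str(idx), (x, y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8, color=color)
    ax.set_aspect("equal")
    if label:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_shape_comparison(shape_a: np.ndarray, shape_b: np.ndarray, ax=None,
                          labels=("group A", "group B")):
    """Overlay two mean-shape wireframes (e.g. two species' consensus wings)."""
    ax = plot_wireframe(shape_a, ax=ax, color="C0", label=labels[0])
    ax = plot_wireframe(shape_b, ax=ax, color="C3", label=labels[1])
    ax.figure.tight_layout()
    return ax
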