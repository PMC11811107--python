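"""Ordinary and generalized Procrustes superimposition.

Shapes here are configurations of k 2-D landmarks, treated modulo
translation, scale and rotation (reflections are disallowed: all specimens
are same-chirality right forewings). Size is measured by centroid size, the
square root of the summed squared distances of the landmarks from their
centroid. Generalized Procrustes analysis (GPA) iteratively superimposes
every configuration on an evolving consensus, then rotates the whole
ensemble onto the consensus's principal axes and projects into the tangent
space at the consensus, where ordinary multivariate statistics apply. For k
2-D landmarks the tangent (shape) space has dimension 2k - 4 — ten
dimensions for the seven-landmark wing scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_landmarks import LabeledDataset, LandmarkConfiguration

__all__ = [
    "centroid_size",
    "procrustes_align",
    "procrustes_distance",
    "GeneralizedProcrustes",
    "AlignedDataset",
    "gpa",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincide; the configuration carries no shape."""


class ConvergenceError(RuntimeError):
    """GPA failed to converge within the iteration cap."""


def _as_shape(x) -> np.ndarray:
    if isinstance(x, LandmarkConfiguration):
        x = x.landmarks
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected a (k, 2) landmark array, got shape {arr.shape}")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinates")
    return arr


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Accepts a :class:`LandmarkConfiguration` or a (k, 2) array. Homogeneous of
    degree 1: scaling the configuration by c scales centroid size by c.
    """
    arr = _as_shape(config)
    centered = arr - arr.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0.0:
        raise DegenerateShapeError("all landmarks coincident: centroid size is 0")
    return cs


def _center_unit(arr: np.ndarray) -> np.ndarray:
    """Centre a shape at the origin and scale it to unit centroid size."""
    centered = arr - arr.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs <= 0.0:
        raise DegenerateShapeError("all landmarks coincident: centroid size is 0")
    return centered / cs


def _optimal_rotation(moving: np.ndarray, target: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal 2x2 matrix R minimizing ||moving @ R - target||_F.

    Via SVD of the cross-covariance H = moving^T target; when reflections
    are disallowed the determinant is forced to +1 by flipping the sign of
    the smallest singular value's contribution.
    """
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        d = np.diag([1.0, -1.0])
        r = u @ d @ vt
    return r


def _rotations_to_target(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Vectorized best proper rotations of many (k,2) shapes onto one target.

    For planar shapes the SVD solution reduces to a closed-form angle:
    with H_i = X_i^T T, theta_i = atan2(H10 - H01, H00 + H11). Equals the
    reflection-free SVD rotation (tested against it).
    """
    h = np.einsum("nki,kj->nij", shapes, target)
    a = h[:, 0, 0] + h[:, 1, 1]
    b = h[:, 1, 0] - h[:, 0, 1]
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    rots = np.empty((shapes.shape[0], 2, 2))
    rots[:, 0, 0] = c
    rots[:, 0, 1] = -s
    rots[:, 1, 0] = s
    rots[:, 1, 1] = c
    return rots


def procrustes_align(moving, target, allow_reflection: bool = False
                     ) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of one shape onto another.

    Both shapes are centred and scaled to unit centroid size; ``moving`` is
    then rotated (never reflected, unless ``allow_reflection``) to minimize
    the summed squared landmark distances to the target.

    Returns
    -------
    aligned : (k, 2) ndarray
        The transformed moving shape.
    residual : float
        sqrt of the minimized sum of squares — the Procrustes (chord)
        distance between the two shapes.
    """
    m = _center_unit(_as_shape(moving))
    t = _center_unit(_as_shape(target))
    if m.shape != t.shape:
        raise ValueError(f"landmark count mismatch: {m.shape[0]} vs {t.shape[0]}")
    r = _optimal_rotation(m, t, allow_reflection=allow_reflection)
    aligned = m @ r
    residual = float(np.sqrt(max(0.0, np.sum((aligned - t) ** 2))))
    return aligned, residual


def procrustes_distance(a, b) -> float:
    """Procrustes distance between two shapes (reflection disallowed).

    The residual of :func:`procrustes_align` after centring and scaling both
    shapes to unit centroid size: zero iff the shapes are
    similarity-equivalent with the same chirality. Symmetric in its
    arguments.
    """
    _, d = procrustes_align(a, b, allow_reflection=False)
    return d


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis


@dataclass
class AlignedDataset:
    """GPA output: consensus, Procrustes coordinates, tangent coordinates.

    Attributes
    ----------
    consensus : (k, 2) ndarray
        Mean shape: unit centroid size, centred, principal-axis aligned.
    aligned_shapes : (n, k, 2) ndarray
        Per-specimen Procrustes coordinates (unit size, centred, rotated).
    tangent_coords : (n, 2k) ndarray
        Row vectors after orthogonal projection onto the tangent hyperplane
        normal to the consensus vector.
    centroid_sizes : (n,) ndarray
        Original (pre-scaling) centroid sizes.
    specimen_ids, labels, classifier
        Carried through from the input dataset.
    """

    consensus: np.ndarray
    aligned_shapes: np.ndarray
    tangent_coords: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    labels: pd.DataFrame
    classifier: str
    n_iterations: int = 0

    @property
    def n(self) -> int:
        return self.aligned_shapes.shape[0]

    @property
    def k(self) -> int:
        return self.aligned_shapes.shape[1]

    @property
    def groups(self) -> np.ndarray:
        return self.labels[self.classifier].to_numpy(dtype=object)

    def group_labels(self) -> list[str]:
        return sorted(set(self.groups))

    def group_mean_shape(self, label: str) -> np.ndarray:
        """Mean Procrustes coordinates of one group (k, 2)."""
        mask = self.groups == label
        if not mask.any():
            raise KeyError(f"no specimens labelled {label!r}")
        return self.aligned_shapes[mask].mean(axis=0)

    def summary(self) -> str:
        counts = pd.Series(self.groups).value_counts()
        lines = [
            "Generalized Procrustes superimposition",
            f"  specimens: {self.n}   landmarks: {self.k}",
            f"  tangent-space dimension (2k-4): {2 * self.k - 4}",
            f"  GPA iterations: {self.n_iterations}",
            f"  centroid size: mean {self.centroid_sizes.mean():.4g}, "
            f"sd {self.centroid_sizes.std(ddof=1):.4g}",
            f"  classifier: {self.classifier}",
        ]
        for g, c in counts.items():
            lines.append(f"    {g}: n={c}")
        return "\n".join(lines)

    # -- serialization (versioned JSON; used by the CLI) --
    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "wingmorph-aligned",
            "version": 1,
            "classifier": self.classifier,
            "consensus": self.consensus.tolist(),
            "aligned_shapes": self.aligned_shapes.tolist(),
            "tangent_coords": self.tangent_coords.tolist(),
            "centroid_sizes": self.centroid_sizes.tolist(),
            "specimen_ids": self.specimen_ids,
            "labels": self.labels.to_dict(orient="list"),
            "n_iterations": self.n_iterations,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignedDataset":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "wingmorph-aligned":
            raise ValueError(f"{path} is not a wingmorph aligned-dataset file")
        return cls(
            consensus=np.array(doc["consensus"]),
            aligned_shapes=np.array(doc["aligned_shapes"]),
            tangent_coords=np.array(doc["tangent_coords"]),
            centroid_sizes=np.array(doc["centroid_sizes"]),
            specimen_ids=list(doc["specimen_ids"]),
            labels=pd.DataFrame(doc["labels"]),
            classifier=doc["classifier"],
            n_iterations=doc.get("n_iterations", 0),
        )


class GeneralizedProcrustes:
    """Generalized Procrustes superimposition model.

    Parameters
    ----------
    dataset : LabeledDataset
        Raw landmark configurations with labels.
    tol : float
        Convergence threshold on the change in total Procrustes sum of
        squares between iterations.
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`.

    Notes
    -----
    The fit (i) centres and scales every configuration to unit centroid
    size, (ii) iterates {rotate each shape onto the consensus; recompute the
    consensus as the coordinate-wise mean rescaled to unit size} from an
    initial consensus equal to the first specimen, (iii) rotates the whole
    ensemble so the consensus's principal axes coincide with the coordinate
    axes (major axis along x, with a deterministic 180-degree flip so that
    consensus landmark 1 has non-positive x), and (iv) projects the aligned
    shapes orthogonally onto the tangent hyperplane normal to the consensus
    vector.
    """

    def __init__(self, dataset: LabeledDataset, tol: float = 1e-10,
                 max_iter: int = 100):
        self.dataset = dataset
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> AlignedDataset:
        ds = self.dataset
        coords = np.asarray(ds.coords, dtype=float)
        n = coords.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least 2 configurations")

        centered = coords - coords.mean(axis=1, keepdims=True)
        sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
        if np.any(sizes <= 0):
            bad = [ds.specimen_ids[i] for i in np.nonzero(sizes <= 0)[0]]
            raise DegenerateShapeError(f"degenerate configurations: {bad}")
        shapes = centered / sizes[:, None, None]

        consensus = shapes[0].copy()
        prev_ss = np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            rots = _rotations_to_target(shapes, consensus)
            shapes = np.einsum("nki,nij->nkj", shapes, rots)
            new_consensus = shapes.mean(axis=0)
            new_consensus -= new_consensus.mean(axis=0)
            new_consensus /= np.sqrt(np.sum(new_consensus**2))
            ss = float(np.sum((shapes - new_consensus) ** 2))
            consensus = new_consensus
            if abs(prev_ss - ss) < self.tol:
                break
            prev_ss = ss
        else:
            raise ConvergenceError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last SS change {abs(prev_ss - ss):.3e})"
            )

        consensus, shapes = self._principal_axis_align(consensus, shapes)

        # Tangent projection (orthogonal): t = v - (v.c) c with |c| = 1.
        c = consensus.reshape(-1)
        v = shapes.reshape(n, -1)
        tangent = v - np.outer(v @ c, c)

        return AlignedDataset(
            consensus=consensus,
            aligned_shapes=shapes,
            tangent_coords=tangent,
            centroid_sizes=sizes,
            specimen_ids=list(ds.specimen_ids),
            labels=ds.labels.copy(),
            classifier=ds.classifier,
            n_iterations=n_iter,
        )

    @staticmethod
    def _principal_axis_align(consensus: np.ndarray, shapes: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
        """Rotate consensus + ensemble so the consensus major axis lies on x.

        Only proper rotations are used (chirality preserved); the remaining
        180-degree ambiguity is resolved by requiring consensus landmark 1 to
        have non-positive x (ties broken on non-positive y).
        """
        cov = consensus.T @ consensus
        evals, evecs = np.linalg.eigh(cov)
        # eigh returns ascending order; put the major axis first.
        evecs = evecs[:, ::-1]
        if np.linalg.det(evecs) < 0:
            evecs[:, 1] = -evecs[:, 1]
        consensus = consensus @ evecs
        shapes = shapes @ evecs
        x1, y1 = consensus[0]
        if x1 > 1e-12 or (abs(x1) <= 1e-12 and y1 > 0):
            consensus = -consensus
            shapes = -shapes
        return consensus, shapes


def gpa(dataset: LabeledDataset, tol: float = 1e-10, max_iter: int = 100
        ) -> AlignedDataset:
    """Run generalized Procrustes analysis on a labelled dataset."""
    return GeneralizedProcrustes(dataset, tol=tol, max_iter=max_iter).fit()
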