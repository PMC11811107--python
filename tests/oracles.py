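"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately written in plain numpy, without touching
the package's own Procrustes code paths, so the two implementations can
disagree.
"""

import numpy as np


def brute_centroid_size(points) -> float:
    """Direct summation: sqrt of summed squared distances to the centroid."""
    pts = np.asarray(points, float)
    cx = sum(p[0] for p in pts) / len(pts)
    cy = sum(p[1] for p in pts) / len(pts)
    total = 0.0
    for x, y in pts:
        total += (x - cx) ** 2 + (y - cy) ** 2
    return float(np.sqrt(total))


def _norm_shape(points) -> np.ndarray:
    pts = np.asarray(points, float)
    pts = pts - pts.mean(axis=0)
    return pts / np.sqrt((pts**2).sum())


def grid_min_residual(moving, target, step_deg: float = 0.001) -> float:
    """Minimum alignment residual over a dense grid of proper rotations.

    Centres and unit-scales both shapes, then explicitly rotates the moving
    shape through every angle in [0, 360) degrees at the given step and
    returns the smallest root-sum-of-squares distance to the target.
    """
    m = _norm_shape(moving)
    t = _norm_shape(target)
    best = np.inf
    thetas = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    for chunk in np.array_split(thetas, max(1, len(thetas) // 30_000)):
        c, s = np.cos(chunk), np.sin(chunk)
        rots = np.stack(
            [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
        )                                        # (a, 2, 2)
        rotated = np.einsum("kj,ajl->akl", m, rots)
        res = np.sqrt(((rotated - t) ** 2).sum(axis=(1, 2)))
        best = min(best, float(res.min()))
    return best


def grid_two_shape_gpa(shape1, shape2, step_deg: float = 0.01):
    """Brute-force two-shape GPA: search the relative rotation directly.

    For each candidate rotation of shape2, the consensus is the unit-scaled
    mean of the pair and the objective is the total Procrustes sum of
    squares about it. Returns (best consensus, best total SS).
    """
    s1 = _norm_shape(shape1)
    s2 = _norm_shape(shape2)
    best_ss, best_c = np.inf, None
    for theta in np.deg2rad(np.arange(0.0, 360.0, step_deg)):
        c, s = np.cos(theta), np.sin(theta)
        r = np.array([[c, -s], [s, c]])
        s2r = s2 @ r
        cons = _norm_shape((s1 + s2r) / 2.0)
        ss = ((s1 - cons) ** 2).sum() + ((s2r - cons) ** 2).sum()
        if ss < best_ss:
            best_ss, best_c = float(ss), cons
    return best_c, best_ss
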