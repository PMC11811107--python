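"""Simulated wing-landmark datasets with controlled statistical structure.

Real forewing landmark data for the invasive/native plusiine screening
problem are not publicly deposited, so this module generates datasets with
the same statistical anatomy: groups of seven-landmark configurations
scattered around group mean shapes (templates), isotropic Gaussian
digitizing noise in shape units, lognormal centroid sizes with optional
group offsets, an optional allometric shape-size component, and random
similarity jitter (rotation/translation/scale) so the output is "raw",
pre-superimposition data.

Built-in templates sketch the discal cell of a plusiine forewing:
``base_wing`` is the reference; ``widened_cell`` displaces landmarks 5-7
outward (a wider discal cell, the contrast that separates *Chrysodeixis
chalcites* from *C. includens*); ``narrow_base`` pulls landmarks 1 and 7
together at the basal end. Template coordinates are versioned constants —
changing them is a breaking change gated by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_landmarks import (
    UNKNOWN,
    LabeledDataset,
    LandmarkConfiguration,
    SpecimenTable,
    assemble_dataset,
)
from .superimposition import _center_unit, procrustes_distance

__all__ = [
    "SyntheticSpec",
    "builtin_template",
    "template_pair",
    "orthogonal_shape_vector",
    "simulate_dataset",
    "simulate_labeled",
    "null_dimorphism_dataset",
]

# Raw (unnormalized) landmark coordinates, wing base at left, apex right.
# Landmarks: 1 base of discal cell; 2-3 along the radial margin; 4 distal
# end of the cell; 5-6 along the cubital margin; 7 lower-basal, near 1.
_BASE_WING_RAW = np.array([
    [0.00, 0.00],    # 1
    [2.00, 0.55],    # 2
    [3.60, 0.75],    # 3
    [4.20, 0.10],    # 4
    [3.50, -0.45],   # 5
    [2.20, -0.60],   # 6
    [0.90, -0.35],   # 7
])

# Outward (downward) displacement of landmarks 5, 6, 7: widens the cell.
_WIDENED_DISPLACEMENT = np.zeros((7, 2))
_WIDENED_DISPLACEMENT[4:7, 1] = [-0.42, -0.48, -0.33]

# Landmarks 1 and 7 pulled toward each other: narrower basal portion.
_NARROW_BASE_DISPLACEMENT = np.zeros((7, 2))
_NARROW_BASE_DISPLACEMENT[0] = [0.18, -0.10]
_NARROW_BASE_DISPLACEMENT[6] = [-0.18, 0.12]

_TEMPLATE_RAW = {
    "base_wing": _BASE_WING_RAW,
    "widened_cell": _BASE_WING_RAW + _WIDENED_DISPLACEMENT,
    "narrow_base": _BASE_WING_RAW + _NARROW_BASE_DISPLACEMENT,
}

_DISPLACEMENTS = {
    "widened_cell": _WIDENED_DISPLACEMENT,
    "narrow_base": _NARROW_BASE_DISPLACEMENT,
}


def builtin_template(name: str) -> np.ndarray:
    """A fixed 7x2 template at unit centroid size, centred at the origin."""
    if name not in _TEMPLATE_RAW:
        raise ValueError(
            f"unknown template {name!r}; choose from {sorted(_TEMPLATE_RAW)}"
        )
    return _center_unit(_TEMPLATE_RAW[name].copy())


def template_pair(distance: float, variant: str = "widened_cell"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Template pair at an exact Procrustes distance apart.

    Scales the variant's displacement field until the Procrustes distance
    between ``base_wing`` and the displaced template equals ``distance``
    (root-finding; deterministic). Useful for power and recovery studies at
    a prescribed effect size.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    base = builtin_template("base_wing")
    if distance == 0:
        return base, base.copy()
    disp = _DISPLACEMENTS[variant]

    def d_of(t: float) -> float:
        shape = _center_unit(_BASE_WING_RAW + t * disp)
        return procrustes_distance(base, shape) - distance

    hi = 1.0
    while d_of(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise ValueError(f"distance {distance} not reachable for {variant!r}")
    t_star = brentq(d_of, 0.0, hi, xtol=1e-12)
    return base, _center_unit(_BASE_WING_RAW + t_star * disp)


def orthogonal_shape_vector(template: np.ndarray) -> np.ndarray:
    """A unit 2k-vector of pure shape change at a template.

    Orthogonal to the similarity directions at the template — the two
    translations, the scaling direction (the template vector itself) and the
    rotation generator (the template rotated 90 degrees) — so the injected
    displacement survives Procrustes superimposition with its norm intact.
    Deterministic: built from a fixed seed pattern by Gram-Schmidt.
    """
    t = _center_unit(np.asarray(template, float))
    k = t.shape[0]
    rot90 = t @ np.array([[0.0, 1.0], [-1.0, 0.0]])
    constraints = [
        np.tile([1.0, 0.0], k) / np.sqrt(k),
        np.tile([0.0, 1.0], k) / np.sqrt(k),
        t.reshape(-1),
        rot90.reshape(-1),
    ]
    v = np.sin(1.0 + np.arange(2 * k, dtype=float))   # fixed seed pattern
    for c in constraints:
        c = c / np.linalg.norm(c)
        v = v - (v @ c) * c
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("seed pattern degenerate for this template")
    return v / norm


@dataclass
class SyntheticSpec:
    """Generative parameters for a simulated landmark dataset.

    Parameters
    ----------
    templates : dict label -> (k, 2) array
        Group mean shapes; normalized to unit centroid size on validation.
    n_per_group : dict label -> int
    noise_sigma : float
        Isotropic per-landmark Gaussian SD in shape units. The default 0.02
        sits between the between-species Procrustes distances observed in
        plusiine wings (roughly 0.09-0.18), giving groups that overlap but
        separate statistically — the regime the analyses are designed for.
    mean_size : float
        Median centroid size in pixels (digitized wing images).
    size_spread : float
        SD of log centroid size (sizes are lognormal).
    size_shift_per_group : dict label -> float
        Additive offsets of mean log size (0 when absent).
    allometry_vector : (2k,) array, optional
        Shape change per unit log centroid size, added as
        ``allometry_vector * (log size - mean log size)``.
    similarity_jitter : bool
        Apply a random rotation (full circle), translation and scale to each
        output configuration, so inputs are raw, pre-GPA data.
    jitter_scale_range : (lo, hi)
        Multiplicative scale jitter range used when jitter is on. The
        default (1, 1) leaves centroid size untouched so size-based analyses
        see exactly the drawn sizes.
    group_classifier : str
        Metadata column that receives the group label (species/genus/sex).
    seed : int
        Generator seed; output is bit-identical for a fixed seed.
    """

    templates: dict[str, np.ndarray]
    n_per_group: dict[str, int]
    noise_sigma: float = 0.02
    mean_size: float = 600.0
    size_spread: float = 0.08
    size_shift_per_group: dict[str, float] = field(default_factory=dict)
    allometry_vector: np.ndarray | None = None
    similarity_jitter: bool = True
    jitter_scale_range: tuple[float, float] = (1.0, 1.0)
    group_classifier: str = "species"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.templates:
            problems.append("templates is empty")
        ks = {np.asarray(t).shape for t in self.templates.values()}
        if len(ks) > 1:
            problems.append(f"templates disagree in shape: {sorted(ks)}")
        if set(self.n_per_group) != set(self.templates):
            problems.append("n_per_group labels do not match template labels")
        if any(n < 1 for n in self.n_per_group.values()):
            problems.append("n_per_group values must be >= 1")
        if self.noise_sigma < 0:
            problems.append("noise_sigma must be >= 0")
        if self.mean_size <= 0:
            problems.append("mean_size must be > 0")
        if self.size_spread < 0:
            problems.append("size_spread must be >= 0")
        if self.jitter_scale_range[0] <= 0:
            problems.append("jitter scale range must be positive")
        if self.allometry_vector is not None:
            k = next(iter(ks))[0] if ks else 0
            if np.asarray(self.allometry_vector).shape != (2 * k,):
                problems.append(
                    f"allometry_vector must have shape ({2 * k},)"
                )
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @property
    def k(self) -> int:
        return next(iter(self.templates.values())).shape[0]


def simulate_dataset(spec: SyntheticSpec
                     ) -> tuple[list[LandmarkConfiguration], SpecimenTable]:
    """Draw a raw landmark dataset from a generative spec.

    Per specimen: shape = template + allometry_vector * (log size - mean
    log size of its group) + iid Gaussian(0, noise_sigma^2) per coordinate;
    the shape is then scaled to the drawn centroid size and, when jitter is
    on, randomly rotated, translated and rescaled. Groups are emitted in
    sorted label order; everything is reproducible bit-identically for a
    fixed seed.
    """
    spec.validate()
    # independent streams: toggling jitter must not perturb shape/size draws
    rng = np.random.default_rng([spec.seed, 0])
    jitter_rng = np.random.default_rng([spec.seed, 1])
    k = spec.k
    configs: list[LandmarkConfiguration] = []
    rows = []
    for label in sorted(spec.templates):
        template = _center_unit(np.asarray(spec.templates[label], float))
        n_g = spec.n_per_group[label]
        mean_log = np.log(spec.mean_size) + spec.size_shift_per_group.get(label, 0.0)
        log_sizes = mean_log + spec.size_spread * rng.standard_normal(n_g)
        noise = rng.standard_normal((n_g, k, 2)) * spec.noise_sigma
        for i in range(n_g):
            shape = template + noise[i]
            if spec.allometry_vector is not None:
                shape = shape + np.asarray(spec.allometry_vector).reshape(k, 2) * (
                    log_sizes[i] - mean_log
                )
            config = _center_unit(shape) * np.exp(log_sizes[i])
            if spec.similarity_jitter:
                theta = jitter_rng.uniform(-np.pi, np.pi)
                c, s = np.cos(theta), np.sin(theta)
                config = config @ np.array([[c, -s], [s, c]])
                lo, hi = spec.jitter_scale_range
                if hi > lo:
                    config = config * jitter_rng.uniform(lo, hi)
                config = config + jitter_rng.uniform(-1, 1, size=2) * spec.mean_size
            sid = f"{label}_{i:04d}"
            configs.append(LandmarkConfiguration(specimen_id=sid, landmarks=config))
            row = {c: UNKNOWN for c in ("species", "genus", "sex", "source")}
            row["specimen_id"] = sid
            row[spec.group_classifier] = label
            row["source"] = "simulated"
            rows.append(row)
    table = SpecimenTable(pd.DataFrame(rows))
    return configs, table


def simulate_labeled(spec: SyntheticSpec) -> LabeledDataset:
    """Simulate and assemble in one step (convenience for analyses)."""
    configs, table = simulate_dataset(spec)
    import warnings

    from .io_landmarks import SmallSampleWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        return assemble_dataset(configs, table, spec.group_classifier)


def null_dimorphism_dataset(spec: SyntheticSpec
                            ) -> tuple[list[LandmarkConfiguration], SpecimenTable]:
    """No-shape-difference dataset for sexual-dimorphism testing.

    Both sexes are drawn from a single template (the first in sorted order);
    only the configured ``size_shift_per_group`` may separate them. Used to
    verify that the pipeline reproduces the "size differs, shape does not"
    pattern expected when males and females share a wing shape.
    """
    if len(spec.templates) != 2 or len(spec.n_per_group) != 2:
        raise ValueError("null dimorphism dataset needs exactly two sex labels")
    labels = sorted(spec.templates)
    shared = np.asarray(spec.templates[labels[0]], float)
    null_spec = SyntheticSpec(
        templates={lbl: shared.copy() for lbl in labels},
        n_per_group=dict(spec.n_per_group),
        noise_sigma=spec.noise_sigma,
        mean_size=spec.mean_size,
        size_spread=spec.size_spread,
        size_shift_per_group=dict(spec.size_shift_per_group),
        allometry_vector=None,
        similarity_jitter=spec.similarity_jitter,
        jitter_scale_range=spec.jitter_scale_range,
        group_classifier="sex",
        seed=spec.seed,
    )
    return simulate_dataset(null_spec)
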