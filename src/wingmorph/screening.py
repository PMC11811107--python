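"""Specimen screening: assign unknown wings to a species/genus group.

A :class:`ScreeningModel` freezes everything a trained CVA needs to place a
new specimen into the training shape space — consensus shape, tangent-space
mean, PCA subspace basis, canonical axes, group means and the pooled
within-group covariance of the CV scores — so prediction never re-runs GPA:
the query wing is superimposed on the stored consensus by ordinary
Procrustes alignment, tangent-projected, and classified by Mahalanobis
distance in canonical-variate space. This mirrors deployment in survey
triage, where the reference model is fitted once and unknowns arrive one at
a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_landmarks import LabeledDataset, LandmarkConfiguration
from .shape_stats import CVA
from .superimposition import (
    AlignedDataset,
    _as_shape,
    _center_unit,
    _optimal_rotation,
    gpa,
)

__all__ = [
    "ScreeningModel",
    "Classification",
    "CrossValidationResults",
    "fit_screening_model",
    "classify_specimen",
    "cross_validate",
]

MODEL_FORMAT = "wingmorph-screening-model"
MODEL_VERSION = 1


@dataclass
class Classification:
    """Outcome of classifying one specimen."""

    specimen_id: str
    label: str
    distances: dict[str, float]
    ambiguous: bool

    def __iter__(self):
        # allow `label, distances, ambiguous = classify_specimen(...)`
        return iter((self.label, self.distances, self.ambiguous))


@dataclass
class ScreeningModel:
    """Frozen CVA-based classifier for landmark configurations.

    ``ambiguity_threshold`` is the relative gap below which the two nearest
    groups are considered indistinguishable: if the second-smallest
    Mahalanobis distance exceeds the smallest by less than this fraction,
    the call is flagged ambiguous (default 10%).
    """

    k: int
    classifier: str
    group_labels: list[str]
    group_sizes: dict[str, int]
    consensus: np.ndarray              # (k, 2)
    tangent_mean: np.ndarray           # (2k,)
    pca_basis: np.ndarray              # (2k, r)
    cv_axes: np.ndarray                # (r, m) subspace -> CV scores
    group_means_cv: np.ndarray         # (g, m)
    within_cov_cv: np.ndarray          # (m, m)
    ambiguity_threshold: float = 0.10
    version: int = MODEL_VERSION
    _within_inv: np.ndarray | None = field(default=None, repr=False)

    def _inv(self) -> np.ndarray:
        if self._within_inv is None:
            self._within_inv = np.linalg.inv(self.within_cov_cv)
        return self._within_inv

    def project(self, config) -> np.ndarray:
        """Map a raw configuration to canonical-variate scores.

        Centres and unit-scales the configuration, rotates it onto the
        stored consensus (ordinary Procrustes, no reflection), projects it
        onto the tangent hyperplane at the consensus, and then through the
        stored PCA basis and canonical axes.
        """
        arr = _as_shape(config)
        if arr.shape[0] != self.k:
            raise ValueError(
                f"model was trained on k={self.k} landmarks, got {arr.shape[0]}"
            )
        shape = _center_unit(arr)
        r = _optimal_rotation(shape, self.consensus, allow_reflection=False)
        v = (shape @ r).reshape(-1)
        c = self.consensus.reshape(-1)
        t = v - (v @ c) * c
        y = (t - self.tangent_mean) @ self.pca_basis
        return y @ self.cv_axes

    def classify(self, config) -> Classification:
        """Nearest-group call by Mahalanobis distance in CV space."""
        score = self.project(config)
        diffs = score - self.group_means_cv
        inv = self._inv()
        d2 = np.einsum("gi,ij,gj->g", diffs, inv, diffs)
        d = np.sqrt(np.clip(d2, 0.0, None))
        order = np.argsort(d)
        d1, d2nd = d[order[0]], d[order[1]]
        if d1 <= 0:
            ambiguous = d2nd <= 0
        else:
            ambiguous = (d2nd - d1) / d1 < self.ambiguity_threshold
        sid = config.specimen_id if isinstance(config, LandmarkConfiguration) else ""
        return Classification(
            specimen_id=sid,
            label=self.group_labels[order[0]],
            distances={g: float(dv) for g, dv in zip(self.group_labels, d)},
            ambiguous=bool(ambiguous),
        )

    # -- serialization --
    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": MODEL_FORMAT,
            "version": self.version,
            "k": self.k,
            "classifier": self.classifier,
            "group_labels": self.group_labels,
            "group_sizes": self.group_sizes,
            "consensus": self.consensus.tolist(),
            "tangent_mean": self.tangent_mean.tolist(),
            "pca_basis": self.pca_basis.tolist(),
            "cv_axes": self.cv_axes.tolist(),
            "group_means_cv": self.group_means_cv.tolist(),
            "within_cov_cv": self.within_cov_cv.tolist(),
            "ambiguity_threshold": self.ambiguity_threshold,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreeningModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path} is not a wingmorph screening model")
        return cls(
            k=doc["k"],
            classifier=doc["classifier"],
            group_labels=list(doc["group_labels"]),
            group_sizes=dict(doc["group_sizes"]),
            consensus=np.array(doc["consensus"]),
            tangent_mean=np.array(doc["tangent_mean"]),
            pca_basis=np.array(doc["pca_basis"]),
            cv_axes=np.array(doc["cv_axes"]),
            group_means_cv=np.array(doc["group_means_cv"]),
            within_cov_cv=np.array(doc["within_cov_cv"]),
            ambiguity_threshold=doc.get("ambiguity_threshold", 0.10),
            version=doc.get("version", MODEL_VERSION),
        )


def fit_screening_model(aligned: AlignedDataset, classifier: str | None = None,
                        ambiguity_threshold: float = 0.10) -> ScreeningModel:
    """Fit a frozen screening model from an aligned training dataset.

    Runs CVA (without permutation tests — only the axes and group structure
    are needed) and stores the alignment frame and projections.
    """
    classifier = classifier or aligned.classifier
    res = CVA(aligned, classifier).fit(n_perm=0, seed=None)

    x = aligned.tangent_coords
    mean = x.mean(axis=0)
    # reconstruct the subspace pieces consistently with the fitted CVA:
    # cv_axes (n_cv, 2k) act on centred tangent rows; factor through the
    # orthonormal PCA basis used during fitting.
    xc = x - mean
    n = x.shape[0]
    cov = (xc.T @ xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    from .shape_stats import RANK_TOL
    rank = int(np.sum(evals > RANK_TOL * max(evals[0], 0)))
    basis = evecs[:, :rank]
    cv_axes_sub = basis.T @ res.cv_axes.T       # (r, n_cv)

    groups = aligned.labels[classifier].to_numpy(dtype=object)
    scores = res.cv_scores
    g_means = np.vstack([scores[groups == lbl].mean(axis=0)
                         for lbl in res.group_labels])
    g = len(res.group_labels)
    within = np.zeros((res.n_cv, res.n_cv))
    for i, lbl in enumerate(res.group_labels):
        dev = scores[groups == lbl] - g_means[i]
        within += dev.T @ dev
    within /= (n - g)

    return ScreeningModel(
        k=aligned.k,
        classifier=classifier,
        group_labels=res.group_labels,
        group_sizes={lbl: int(np.sum(groups == lbl)) for lbl in res.group_labels},
        consensus=np.ascontiguousarray(aligned.consensus),
        tangent_mean=np.ascontiguousarray(mean),
        # contiguous copies so a saved/reloaded model follows the identical
        # BLAS paths and reproduces predictions bit-for-bit
        pca_basis=np.ascontiguousarray(basis),
        cv_axes=np.ascontiguousarray(cv_axes_sub),
        group_means_cv=g_means,
        within_cov_cv=within,
        ambiguity_threshold=ambiguity_threshold,
    )


def classify_specimen(model: ScreeningModel, config
                      ) -> Classification:
    """Classify one configuration with a fitted screening model."""
    return model.classify(config)


@dataclass
class CrossValidationResults:
    """Leave-one-out cross-validation of the screening pipeline."""

    confusion: pd.DataFrame            # rows: true, cols: predicted
    per_class_accuracy: pd.Series
    accuracy: float
    n_ambiguous: int

    def summary(self) -> str:
        lines = [
            "Leave-one-out cross-validated classification",
            f"  overall accuracy: {100 * self.accuracy:.1f}%"
            f"   (ambiguous calls: {self.n_ambiguous})",
            "  confusion matrix (rows true, columns predicted):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)


def cross_validate(dataset: LabeledDataset, classifier: str | None = None,
                   seed: int | None = None) -> CrossValidationResults:
    """Leave-one-out cross-validation: refit GPA + CVA without each specimen.

    Each held-out wing is classified by a model trained on all others, so
    the reported accuracy is an honest estimate of screening reliability.
    ``seed`` is recorded for API symmetry; the procedure is deterministic.
    """
    classifier = classifier or dataset.classifier
    groups = dataset.labels[classifier].to_numpy(dtype=object)
    labels = sorted(set(groups))
    counts = pd.Series(groups).value_counts()
    too_small = [g for g in labels if counts[g] < 3]
    if too_small:
        raise ValueError(f"groups too small for leave-one-out: {too_small}")

    n = dataset.n
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    n_ambiguous = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = LabeledDataset(
            coords=dataset.coords[keep],
            specimen_ids=[s for j, s in enumerate(dataset.specimen_ids) if j != i],
            labels=dataset.labels.iloc[keep].reset_index(drop=True),
            classifier=classifier,
        )
        model = fit_screening_model(gpa(train), classifier)
        call = model.classify(dataset.coords[i])
        confusion.loc[groups[i], call.label] += 1
        n_ambiguous += call.ambiguous

    correct = np.trace(confusion.to_numpy())
    per_class = pd.Series(
        {g: confusion.loc[g, g] / confusion.loc[g].sum() for g in labels}
    )
    return CrossValidationResults(
        confusion=confusion,
        per_class_accuracy=per_class,
        accuracy=correct / n,
        n_ambiguous=n_ambiguous,
    )
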