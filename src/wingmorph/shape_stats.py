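"""Statistical engines on tangent-space shape coordinates.

Four analyses, each a model class whose ``fit()`` returns a results object
with a ``summary()`` table, plus functional wrappers under the classic
names:

* :class:`ShapePCA` — eigenanalysis of the tangent-coordinate covariance.
* :class:`AllometryRegression` — multivariate regression of shape on
  centroid size, with a permutation test of the explained fraction.
* :class:`ProcrustesAnova` — one-way ANOVA of centroid size and a
  Goodall-style F for shape (sums of squares over all coordinates, degrees
  of freedom multiplied by the shape-space dimension 2k - 4), with both
  parametric and permutation p-values.
* :class:`CVA` — canonical variate analysis in the full-rank PCA subspace,
  with Mahalanobis and Procrustes distances among groups and per-pair
  permutation tests.

Permutation p-values use the (b + 1) / (N + 1) convention, so a p-value is
never exactly zero; every analysis draws from a single generator seeded by
the caller, and the seed is recorded in the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .superimposition import AlignedDataset, procrustes_distance

__all__ = [
    "ShapePCA", "ShapePCAResults", "shape_pca",
    "AllometryRegression", "AllometryResults", "allometry_regression",
    "ProcrustesAnova", "ProcrustesAnovaResults", "procrustes_anova",
    "CVA", "CVAResults", "cva",
]

#: Relative eigenvalue threshold separating real shape dimensions from
#: numerical zeros introduced by the 4 similarity constraints.
RANK_TOL = 1e-8


def _fix_signs(vectors: np.ndarray, scores: np.ndarray | None = None):
    """Deterministic sign convention: largest-|loading| entry positive.

    ``vectors`` has one axis per row; score columns are flipped to match.
    """
    for i, v in enumerate(vectors):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            vectors[i] = -v
            if scores is not None:
                scores[:, i] = -scores[:, i]
    return vectors, scores


def _group_codes(groups: np.ndarray) -> tuple[np.ndarray, list[str], np.ndarray]:
    labels = sorted(set(groups))
    lookup = {g: i for i, g in enumerate(labels)}
    codes = np.array([lookup[g] for g in groups])
    counts = np.bincount(codes, minlength=len(labels))
    return codes, labels, counts


def _between_ss(x: np.ndarray, codes: np.ndarray, g: int) -> float:
    """Between-group sum of squares of multivariate rows, about the grand mean."""
    grand = x.mean(axis=0)
    ss = 0.0
    for j in range(g):
        rows = x[codes == j]
        ss += len(rows) * float(np.sum((rows.mean(axis=0) - grand) ** 2))
    return ss


def _permuted_between_ss(x: np.ndarray, codes: np.ndarray, g: int,
                         n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Between-group SS for ``n_perm`` random relabellings, vectorized.

    The total SS is invariant under relabelling, so the between-group SS is
    a sufficient permutation statistic for the Goodall F.
    """
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    perm_codes = np.tile(codes, (n_perm, 1))
    perm_codes = rng.permuted(perm_codes, axis=1)
    ss = np.zeros(n_perm)
    for j in range(g):
        mask = perm_codes == j
        n_j = mask[0].sum()
        sums = mask.astype(float) @ xc          # (n_perm, p) group sums
        ss += np.sum(sums**2, axis=1) / n_j
    return ss


# ---------------------------------------------------------------------------
# Shape PCA


@dataclass
class ShapePCAResults:
    """Eigenanalysis of the tangent-coordinate covariance matrix.

    ``eigenvectors`` holds one 2k-dimensional loading row per component;
    ``scores`` are centred specimen scores, one column per component.
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    groups: np.ndarray | None = None

    @property
    def n_nonzero(self) -> int:
        """Number of eigenvalues above ``RANK_TOL`` times the largest."""
        if self.eigenvalues[0] <= 0:
            return 0
        return int(np.sum(self.eigenvalues > RANK_TOL * self.eigenvalues[0]))

    def summary(self) -> str:
        lines = [
            "Principal component analysis of shape (covariance matrix)",
            f"  specimens: {self.scores.shape[0]}   "
            f"shape-space dimensions: {self.n_nonzero}",
            "  PC   eigenvalue    % variance   cumulative %",
        ]
        cum = 0.0
        for i in range(self.n_nonzero):
            cum += self.percent_variance[i]
            lines.append(
                f"  {i + 1:<4d} {self.eigenvalues[i]:<12.6g} "
                f"{self.percent_variance[i]:<12.4g} {cum:.4g}"
            )
        return "\n".join(lines)

    def plot(self, components=(0, 1), ax=None, ellipse: float = 0.9):
        from .plotting import plot_scores
        return plot_scores(
            self.scores[:, list(components)], self.groups, ax=ax,
            ellipse=ellipse,
            xlabel=f"PC{components[0] + 1} ({self.percent_variance[components[0]]:.1f}%)",
            ylabel=f"PC{components[1] + 1} ({self.percent_variance[components[1]]:.1f}%)",
        )


class ShapePCA:
    """Shape PCA model over an aligned dataset's tangent coordinates."""

    def __init__(self, aligned: AlignedDataset):
        self.aligned = aligned

    def fit(self) -> ShapePCAResults:
        x = self.aligned.tangent_coords
        n = x.shape[0]
        if n < 3:
            raise ValueError("shape PCA needs at least 3 specimens")
        mean = x.mean(axis=0)
        xc = x - mean
        cov = (xc.T @ xc) / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        scores = xc @ evecs
        loadings, scores = _fix_signs(evecs.T.copy(), scores)
        total = evals.sum()
        percent = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
        return ShapePCAResults(
            eigenvalues=evals,
            percent_variance=percent,
            eigenvectors=loadings,
            scores=scores,
            mean=mean,
            groups=self.aligned.groups,
        )


def shape_pca(aligned: AlignedDataset) -> ShapePCAResults:
    """PCA of the tangent-coordinate covariance (n - 1 divisor)."""
    return ShapePCA(aligned).fit()


# ---------------------------------------------------------------------------
# Allometry: multivariate regression of shape on centroid size


@dataclass
class AllometryResults:
    """Multivariate regression of shape coordinates on centroid size."""

    percent_predicted: float
    p_value: float
    coefficient_vector: np.ndarray
    use_log_size: bool
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        size_name = "log centroid size" if self.use_log_size else "centroid size"
        return (
            "Multivariate regression of shape on size\n"
            f"  independent variable: {size_name}\n"
            f"  % predicted: {self.percent_predicted:.4f}\n"
            f"  permutation P ({self.n_perm} rounds): {self.p_value:.4f}"
        )


class AllometryRegression:
    """Shape-on-size regression model with a permutation test.

    Each tangent coordinate is regressed on centroid size (raw by default;
    set ``use_log_size`` to regress on log size). ``percent_predicted`` is
    100 times the ratio of the explained sum of squares, pooled over all
    coordinates, to the total sum of squares. Significance comes from
    permuting the size values among specimens.
    """

    def __init__(self, aligned: AlignedDataset, use_log_size: bool = False):
        self.aligned = aligned
        self.use_log_size = use_log_size

    def fit(self, n_perm: int = 10_000, seed: int | None = None
            ) -> AllometryResults:
        x = self.aligned.tangent_coords
        n = x.shape[0]
        if n < 3:
            raise ValueError("allometry regression needs at least 3 specimens")
        s = np.asarray(self.aligned.centroid_sizes, dtype=float)
        if self.use_log_size:
            s = np.log(s)
        sc = s - s.mean()
        ss_size = float(sc @ sc)
        if ss_size <= 0:
            raise ValueError("centroid sizes are all equal; cannot regress on size")
        xc = x - x.mean(axis=0)
        ss_total = float(np.sum(xc**2))
        beta = (sc @ xc) / ss_size
        ss_model = float(beta @ beta) * ss_size
        observed = 100.0 * ss_model / ss_total

        rng = np.random.default_rng(seed)
        perm_s = np.tile(sc, (n_perm, 1))
        perm_s = rng.permuted(perm_s, axis=1)
        cross = perm_s @ xc                      # (n_perm, 2k)
        perm_stat = 100.0 * np.sum(cross**2, axis=1) / ss_size / ss_total
        p = (np.sum(perm_stat >= observed) + 1) / (n_perm + 1)

        return AllometryResults(
            percent_predicted=observed,
            p_value=float(p),
            coefficient_vector=beta,
            use_log_size=self.use_log_size,
            n_perm=n_perm,
            seed=seed,
        )


def allometry_regression(aligned: AlignedDataset, n_perm: int = 10_000,
                         seed: int | None = None, use_log_size: bool = False
                         ) -> AllometryResults:
    """Regress shape on centroid size; permutation-test the explained fraction."""
    return AllometryRegression(aligned, use_log_size=use_log_size).fit(
        n_perm=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# Procrustes ANOVA


@dataclass
class ProcrustesAnovaResults:
    """One-way ANOVA of centroid size and Goodall F of shape by group."""

    classifier: str
    group_labels: list[str]
    group_sizes: np.ndarray
    # centroid size
    size_ss_effect: float
    size_ss_error: float
    size_df: tuple[int, int]
    size_f: float
    size_p: float
    # shape
    shape_ss_effect: float
    shape_ss_error: float
    shape_df: tuple[int, int]
    shape_f: float
    shape_p_parametric: float
    shape_p_permutation: float
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"Procrustes ANOVA (classifier: {self.classifier}; "
            f"groups: {', '.join(map(str, self.group_labels))})\n"
            "  effect          SS          df        F         P\n"
            f"  centroid size   {self.size_ss_effect:<11.5g} "
            f"{self.size_df[0]:<9d} {self.size_f:<9.4g} {self.size_p:.4g}\n"
            f"  size error      {self.size_ss_error:<11.5g} {self.size_df[1]:<9d}\n"
            f"  shape           {self.shape_ss_effect:<11.5g} "
            f"{self.shape_df[0]:<9d} {self.shape_f:<9.4g} "
            f"{self.shape_p_parametric:.4g} "
            f"(permutation: {self.shape_p_permutation:.4g})\n"
            f"  shape error     {self.shape_ss_error:<11.5g} {self.shape_df[1]:<9d}"
        )


class ProcrustesAnova:
    """Group-difference test for centroid size and shape.

    Shape uses Goodall's approach: Procrustes (tangent-coordinate) sums of
    squares pooled over all coordinates, with both degrees of freedom
    multiplied by the shape-space dimension 2k - 4. The permutation test
    shuffles group labels; the between-group SS is the permutation statistic
    (the total SS is label-invariant, so this is equivalent to permuting F).
    """

    def __init__(self, aligned: AlignedDataset, classifier: str | None = None):
        self.aligned = aligned
        self.classifier = classifier or aligned.classifier

    def fit(self, n_perm: int = 10_000, seed: int | None = None
            ) -> ProcrustesAnovaResults:
        aligned = self.aligned
        groups = aligned.labels[self.classifier].to_numpy(dtype=object)
        codes, labels, counts = _group_codes(groups)
        g = len(labels)
        n = len(codes)
        if g < 2:
            raise ValueError("Procrustes ANOVA needs at least 2 groups")
        if counts.min() < 2:
            small = [labels[j] for j in np.nonzero(counts < 2)[0]]
            raise ValueError(f"groups with fewer than 2 specimens: {small}")

        # centroid size: ordinary one-way ANOVA
        s = np.asarray(aligned.centroid_sizes, dtype=float)
        size_ssb = _between_ss(s[:, None], codes, g)
        size_sst = float(np.sum((s - s.mean()) ** 2))
        size_ssw = size_sst - size_ssb
        size_df = (g - 1, n - g)
        size_f = (size_ssb / size_df[0]) / (size_ssw / size_df[1])
        size_p = float(stats.f.sf(size_f, *size_df))

        # shape: Goodall F on tangent coordinates
        x = aligned.tangent_coords
        dims = 2 * aligned.k - 4
        shape_ssb = _between_ss(x, codes, g)
        shape_sst = float(np.sum((x - x.mean(axis=0)) ** 2))
        shape_ssw = shape_sst - shape_ssb
        shape_df = ((g - 1) * dims, (n - g) * dims)
        shape_f = (shape_ssb / shape_df[0]) / (shape_ssw / shape_df[1])
        shape_p_par = float(stats.f.sf(shape_f, *shape_df))

        rng = np.random.default_rng(seed)
        perm_ssb = _permuted_between_ss(x, codes, g, n_perm, rng)
        shape_p_perm = float((np.sum(perm_ssb >= shape_ssb) + 1) / (n_perm + 1))

        return ProcrustesAnovaResults(
            classifier=self.classifier,
            group_labels=labels,
            group_sizes=counts,
            size_ss_effect=size_ssb,
            size_ss_error=size_ssw,
            size_df=size_df,
            size_f=float(size_f),
            size_p=size_p,
            shape_ss_effect=shape_ssb,
            shape_ss_error=shape_ssw,
            shape_df=shape_df,
            shape_f=float(shape_f),
            shape_p_parametric=shape_p_par,
            shape_p_permutation=shape_p_perm,
            n_perm=n_perm,
            seed=seed,
        )


def procrustes_anova(aligned: AlignedDataset, classifier: str | None = None,
                     n_perm: int = 10_000, seed: int | None = None
                     ) -> ProcrustesAnovaResults:
    """Procrustes ANOVA of centroid size and shape for a grouping classifier."""
    return ProcrustesAnova(aligned, classifier).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Canonical variate analysis


@dataclass
class CVAResults:
    """Canonical variate analysis of shape by group.

    ``cv_axes`` holds one 2k-dimensional tangent-space loading row per
    canonical variate, scaled so CV scores have unit pooled within-group
    variance. Distance matrices are symmetric pandas DataFrames indexed by
    group label.
    """

    classifier: str
    group_labels: list[str]
    n_cv: int
    cv_eigenvalues: np.ndarray
    percent_variation: np.ndarray
    cv_scores: np.ndarray
    cv_axes: np.ndarray
    mahalanobis: pd.DataFrame
    procrustes_dist: pd.DataFrame
    perm_p: pd.DataFrame
    overall_f: float
    overall_p: float
    groups: np.ndarray = field(repr=False, default=None)
    n_perm: int = 0
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            f"Canonical variate analysis (classifier: {self.classifier})",
            f"  groups: {', '.join(map(str, self.group_labels))}",
            f"  canonical variates: {self.n_cv}",
        ]
        for i in range(self.n_cv):
            lines.append(
                f"    CV{i + 1}: eigenvalue {self.cv_eigenvalues[i]:.4g}, "
                f"{self.percent_variation[i]:.1f}% of between-group variation"
            )
        lines.append(f"  overall Goodall F: {self.overall_f:.4f} "
                     f"(P = {self.overall_p:.4g})")
        lines.append("  Procrustes distances among groups:")
        lines.append(self.procrustes_dist.round(4).to_string())
        if self.n_perm:
            lines.append(f"  permutation P ({self.n_perm} rounds):")
            lines.append(self.perm_p.to_string())
        return "\n".join(lines)

    def plot(self, components=(0, 1), ax=None, ellipse: float = 0.9):
        from .plotting import plot_scores
        comps = [c for c in components if c < self.n_cv]
        scores = self.cv_scores[:, comps]
        if scores.shape[1] == 1:
            scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
        return plot_scores(
            scores, self.groups, ax=ax, ellipse=ellipse,
            xlabel=f"CV1 ({self.percent_variation[0]:.1f}%)",
            ylabel=("CV2" if self.n_cv > 1 else ""),
        )


class CVA:
    """Canonical variate analysis model.

    Tangent coordinates are first projected onto the full-rank PCA subspace
    (eigenvalues above ``RANK_TOL`` of the largest) because the raw 2k
    tangent coordinates are rank-deficient by construction (rank 2k - 4),
    which would make the pooled within-group covariance singular. The
    canonical axes solve the generalized eigenproblem of between-group
    versus pooled within-group covariance in that subspace; at most
    (groups - 1) variates carry between-group variation.

    Pairwise permutation tests shuffle the two groups' labels and compare
    the squared tangent-space distance between group means (rank-equivalent
    to the Procrustes distance between mean shapes in the small-variation
    regime wings occupy).
    """

    def __init__(self, aligned: AlignedDataset, classifier: str | None = None):
        self.aligned = aligned
        self.classifier = classifier or aligned.classifier

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> CVAResults:
        aligned = self.aligned
        groups = aligned.labels[self.classifier].to_numpy(dtype=object)
        codes, labels, counts = _group_codes(groups)
        g = len(labels)
        n = len(codes)
        if g < 2:
            raise ValueError("CVA needs at least 2 groups")
        if counts.min() < 2:
            small = [labels[j] for j in np.nonzero(counts < 2)[0]]
            raise ValueError(f"groups with a single specimen: {small}")

        x = aligned.tangent_coords
        mean = x.mean(axis=0)
        xc = x - mean
        cov = (xc.T @ xc) / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rank = int(np.sum(evals > RANK_TOL * max(evals[0], 0)))
        basis = evecs[:, :rank]                  # (2k, r) orthonormal
        y = xc @ basis                           # (n, r)
        if n <= rank:
            raise ValueError(
                f"need more than {rank} specimens for a rank-{rank} subspace"
            )

        # scatter matrices in the subspace
        w_s = np.zeros((rank, rank))
        b_s = np.zeros((rank, rank))
        means = np.zeros((g, rank))
        for j in range(g):
            rows = y[codes == j]
            means[j] = rows.mean(axis=0)
            dev = rows - means[j]
            w_s += dev.T @ dev
            b_s += counts[j] * np.outer(means[j], means[j])
        try:
            scipy.linalg.cholesky(w_s)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError(
                "pooled within-group covariance is singular after PCA "
                "projection; reduce dimensionality or add specimens"
            ) from exc

        evals_cv, vecs_cv = scipy.linalg.eigh(b_s, w_s)
        order = np.argsort(evals_cv)[::-1]
        evals_cv, vecs_cv = evals_cv[order], vecs_cv[:, order]
        n_cv = min(g - 1, rank)
        evals_cv = np.clip(evals_cv[:n_cv], 0.0, None)
        # eigh normalizes v' W_s v = 1; rescale so pooled within-group
        # variance of the scores is 1.
        axes_sub = vecs_cv[:, :n_cv] * np.sqrt(n - g)
        scores = y @ axes_sub
        axes_full = (basis @ axes_sub).T         # (n_cv, 2k)
        axes_full, scores = _fix_signs(axes_full, scores)
        total = evals_cv.sum()
        percent = 100.0 * evals_cv / total if total > 0 else np.zeros(n_cv)

        # distances among groups
        w_cov = w_s / (n - g)
        w_inv = np.linalg.inv(w_cov)
        maha = np.zeros((g, g))
        pdist = np.zeros((g, g))
        mean_shapes = [aligned.group_mean_shape(lbl) for lbl in labels]
        for i in range(g):
            for j in range(i + 1, g):
                d = means[i] - means[j]
                maha[i, j] = maha[j, i] = np.sqrt(d @ w_inv @ d)
                pd_ij = procrustes_distance(mean_shapes[i], mean_shapes[j])
                pdist[i, j] = pdist[j, i] = pd_ij

        # per-pair permutation tests
        perm = np.full((g, g), np.nan)
        np.fill_diagonal(perm, 0.0)
        if n_perm > 0:
            rng = np.random.default_rng(seed)
            for i in range(g):
                for j in range(i + 1, g):
                    p = _pairwise_mean_distance_test(
                        y[codes == i], y[codes == j], n_perm, rng
                    )
                    perm[i, j] = perm[j, i] = p

        # overall Goodall F on tangent coordinates (matches Procrustes ANOVA)
        dims = 2 * aligned.k - 4
        ssb = _between_ss(x, codes, g)
        sst = float(np.sum(xc**2))
        ssw = sst - ssb
        df = ((g - 1) * dims, (n - g) * dims)
        overall_f = (ssb / df[0]) / (ssw / df[1])
        overall_p = float(stats.f.sf(overall_f, *df))

        def _frame(a):
            return pd.DataFrame(a, index=labels, columns=labels)

        return CVAResults(
            classifier=self.classifier,
            group_labels=labels,
            n_cv=n_cv,
            cv_eigenvalues=evals_cv,
            percent_variation=percent,
            cv_scores=scores,
            cv_axes=axes_full,
            mahalanobis=_frame(maha),
            procrustes_dist=_frame(pdist),
            perm_p=_frame(perm),
            overall_f=float(overall_f),
            overall_p=overall_p,
            groups=groups,
            n_perm=n_perm,
            seed=seed,
        )


def _pairwise_mean_distance_test(y1: np.ndarray, y2: np.ndarray,
                                 n_perm: int, rng: np.random.Generator,
                                 chunk: int = 2_000) -> float:
    """Two-group permutation test on squared distance between group means."""
    n1 = len(y1)
    pooled = np.vstack([y1, y2])
    n12 = len(pooled)
    total = pooled.sum(axis=0)
    obs = float(np.sum((y1.mean(axis=0) - y2.mean(axis=0)) ** 2))
    count = 0
    remaining = n_perm
    while remaining > 0:
        b = min(chunk, remaining)
        idx = np.argsort(rng.random((b, n12)), axis=1)[:, :n1]
        sums1 = pooled[idx].sum(axis=1)
        m1 = sums1 / n1
        m2 = (total - sums1) / (n12 - n1)
        stat = np.sum((m1 - m2) ** 2, axis=1)
        count += int(np.sum(stat >= obs))
        remaining -= b
    return (count + 1) / (n_perm + 1)


def cva(aligned: AlignedDataset, classifier: str | None = None,
        n_perm: int = 10_000, seed: int | None = None) -> CVAResults:
    """Canonical variate analysis with per-pair permutation tests."""
    return CVA(aligned, classifier).fit(n_perm=n_perm, seed=seed)
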