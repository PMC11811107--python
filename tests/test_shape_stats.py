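import numpy as np
import pandas as pd
import pytest

import wingmorph as wm
from wingmorph.shape_stats import _between_ss


def make_aligned(tangent, groups, sizes=None, k=7, consensus=None):
    """Hand-assemble an AlignedDataset from raw tangent rows (for oracles)."""
    tangent = np.asarray(tangent, float)
    n = tangent.shape[0]
    if consensus is None:
        consensus = wm.builtin_template("base_wing")
    aligned_shapes = consensus[None] + tangent.reshape(n, k, 2)
    labels = pd.DataFrame(
        {
            "specimen_id": [f"s{i}" for i in range(n)],
            "species": list(groups),
            "genus": ["g"] * n,
            "sex": ["male"] * n,
            "source": ["sim"] * n,
        }
    )
    return wm.AlignedDataset(
        consensus=consensus,
        aligned_shapes=aligned_shapes,
        tangent_coords=tangent,
        centroid_sizes=np.ones(n) if sizes is None else np.asarray(sizes, float),
        specimen_ids=list(labels["specimen_id"]),
        labels=labels,
        classifier="species",
    )


class TestShapePCA:
    def test_variance_conservation_and_normalisation(self, aligned_two_group):
        res = wm.shape_pca(aligned_two_group)
        x = aligned_two_group.tangent_coords
        xc = x - x.mean(axis=0)
        total = np.trace(xc.T @ xc / (len(x) - 1))
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-9)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-9

    def test_seven_landmarks_span_ten_dimensions(self, aligned_two_group):
        assert wm.shape_pca(aligned_two_group).n_nonzero == 10

    def test_scores_reproduce_tangent_distances(self, aligned_two_group):
        """PCA is a rotation: pairwise distances of scores equal those of
        the centred tangent rows."""
        res = wm.shape_pca(aligned_two_group)
        x = aligned_two_group.tangent_coords
        xc = x - x.mean(axis=0)
        for i, j in [(0, 1), (3, 40), (10, 22)]:
            assert np.linalg.norm(res.scores[i] - res.scores[j]) == pytest.approx(
                np.linalg.norm(xc[i] - xc[j]), rel=1e-9
            )

    def test_isotropic_noise_gives_spherical_spectrum(self, base_template):
        """Under the isotropic model the 10 tangent eigenvalues are equal in
        expectation; at n = 5000 the sorted sample eigenvalues sit within
        the 15% band around their mean allowed by eigenvalue spreading."""
        spec = wm.SyntheticSpec(
            templates={"A": base_template},
            n_per_group={"A": 5000},
            noise_sigma=0.01,
            seed=99,
        )
        res = wm.shape_pca(wm.gpa(wm.simulate_labeled(spec)))
        ev = res.eigenvalues[:10]
        assert np.abs(ev / ev.mean() - 1).max() < 0.15

    def test_too_few_specimens_rejected(self, base_template):
        al = make_aligned(np.zeros((2, 14)) + np.eye(2, 14) * 0.01, ["a", "b"])
        with pytest.raises(ValueError):
            wm.shape_pca(al)


class TestAllometryRegression:
    def test_exact_linear_signal_fully_predicted(self):
        """Tangent rows exactly linear in centroid size -> 100% predicted."""
        rng = np.random.default_rng(5)
        sizes = rng.uniform(100, 900, size=40)
        beta = rng.normal(size=14) * 0.001
        tangent = np.outer(sizes - sizes.mean(), beta)
        al = make_aligned(tangent, ["a"] * 40, sizes=sizes)
        res = wm.allometry_regression(al, n_perm=99, seed=1)
        assert res.percent_predicted == pytest.approx(100.0, abs=1e-6)

    def test_generator_log_size_signal_recovered(self, base_template):
        """Noiseless allometric wings: log-size regression explains
        essentially everything; raw-size regression slightly less (the
        generator acts on log size, the default regressor is raw size)."""
        vec = wm.orthogonal_shape_vector(base_template) * 0.1
        spec = wm.SyntheticSpec(
            templates={"A": base_template},
            n_per_group={"A": 60},
            noise_sigma=0.0,
            size_spread=0.08,
            allometry_vector=vec,
            seed=3,
        )
        al = wm.gpa(wm.simulate_labeled(spec))
        on_log = wm.allometry_regression(al, n_perm=99, seed=1, use_log_size=True)
        on_raw = wm.allometry_regression(al, n_perm=99, seed=1)
        assert on_log.percent_predicted > 99.99
        assert 99.0 < on_raw.percent_predicted < on_log.percent_predicted

    def test_permutation_p_reproducible_and_bounded(self, aligned_two_group):
        r1 = wm.allometry_regression(aligned_two_group, n_perm=499, seed=7)
        r2 = wm.allometry_regression(aligned_two_group, n_perm=499, seed=7)
        assert r1.p_value == r2.p_value
        assert 1 / 500 <= r1.p_value <= 1.0

    def test_equal_sizes_rejected(self):
        al = make_aligned(np.random.default_rng(0).normal(size=(10, 14)) * 0.01,
                          ["a"] * 10, sizes=np.full(10, 5.0))
        with pytest.raises(ValueError, match="equal"):
            wm.allometry_regression(al, n_perm=9, seed=0)


class TestProcrustesAnova:
    def test_degrees_of_freedom_for_two_species_of_47(self, aligned_two_group):
        res = wm.procrustes_anova(aligned_two_group, n_perm=99, seed=0)
        assert res.shape_df == (10, 450)
        assert res.size_df == (1, 45)

    def test_goodall_f_matches_distance_based_form(self, aligned_two_group):
        """Two independent routes to the two-group Goodall F: pooled SS
        decomposition vs the n1*n2/n times squared mean-distance identity."""
        res = wm.procrustes_anova(aligned_two_group, n_perm=99, seed=0)
        x = aligned_two_group.tangent_coords
        g = aligned_two_group.groups
        xa, xb = x[g == "A"], x[g == "B"]
        n1, n2 = len(xa), len(xb)
        d2 = float(np.sum((xa.mean(0) - xb.mean(0)) ** 2))
        ssb = n1 * n2 / (n1 + n2) * d2
        ssw = float(np.sum((xa - xa.mean(0)) ** 2) + np.sum((xb - xb.mean(0)) ** 2))
        dims = 10
        f_dist = (ssb / dims) / (ssw / ((n1 + n2 - 2) * dims))
        assert res.shape_f == pytest.approx(f_dist, rel=1e-8)
        assert res.shape_ss_effect == pytest.approx(ssb, rel=1e-8)

    def test_strong_effect_detected(self, aligned_two_group):
        res = wm.procrustes_anova(aligned_two_group, n_perm=999, seed=3)
        assert res.shape_p_permutation <= 0.001
        assert res.shape_p_parametric < 1e-10

    def test_permutation_p_bit_reproducible(self, aligned_two_group):
        p1 = wm.procrustes_anova(aligned_two_group, n_perm=499, seed=11)
        p2 = wm.procrustes_anova(aligned_two_group, n_perm=499, seed=11)
        assert p1.shape_p_permutation == p2.shape_p_permutation

    def test_group_of_one_rejected(self, base_template):
        tangent = np.random.default_rng(1).normal(size=(5, 14)) * 0.01
        al = make_aligned(tangent, ["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            wm.procrustes_anova(al, n_perm=9, seed=0)

    def test_single_group_rejected(self, base_template):
        tangent = np.random.default_rng(1).normal(size=(5, 14)) * 0.01
        al = make_aligned(tangent, ["a"] * 5)
        with pytest.raises(ValueError, match="2 groups"):
            wm.procrustes_anova(al, n_perm=9, seed=0)


class TestCVA:
    def test_two_groups_one_variate_all_variation(self, aligned_two_group):
        res = wm.cva(aligned_two_group, n_perm=99, seed=0)
        assert res.n_cv == 1
        np.testing.assert_allclose(res.percent_variation, [100.0])

    def test_five_groups_four_variates(self, base_template):
        rng = np.random.default_rng(12)
        templates, counts = {}, {}
        for i, name in enumerate("ABCDE"):
            t = base_template + rng.normal(size=(7, 2)) * 0.03
            templates[name] = t
            counts[name] = 16
        spec = wm.SyntheticSpec(
            templates=templates, n_per_group=counts, noise_sigma=0.02, seed=13
        )
        res = wm.cva(wm.gpa(wm.simulate_labeled(spec)), n_perm=0)
        assert res.n_cv == 4
        assert res.percent_variation.sum() == pytest.approx(100.0)

    def test_mahalanobis_matches_hand_computed_toy(self):
        """Two 2-D clouds embedded in tangent space. Group deviations are
        (+-0.5, +-0.5), so the pooled within covariance is I/3 and the
        Mahalanobis distance between means (3, 2) apart is sqrt(3*13)."""
        a2d = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        b2d = a2d + [3.0, 2.0]
        data = np.vstack([a2d, b2d])
        tangent = np.zeros((8, 14))
        tangent[:, 0] = data[:, 0] * 0.001
        tangent[:, 1] = data[:, 1] * 0.001  # scaled orthonormal embedding
        al = make_aligned(tangent, ["a"] * 4 + ["b"] * 4)
        res = wm.cva(al, n_perm=0)
        expected = np.sqrt(3 * (3**2 + 2**2))  # scale cancels in Mahalanobis
        assert res.mahalanobis.loc["a", "b"] == pytest.approx(expected, rel=1e-9)

    def test_two_group_axis_collinear_with_fisher_lda(self, aligned_two_group):
        """Independent cross-check: scikit-learn's Fisher discriminant on the
        PCA-projected tangent coordinates points along the single CV axis."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        res = wm.cva(aligned_two_group, n_perm=0)
        x = aligned_two_group.tangent_coords
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (len(x) - 1))
        basis = evecs[:, np.argsort(evals)[::-1][:10]]
        lda = LinearDiscriminantAnalysis(solver="eigen")
        lda.fit(xc @ basis, aligned_two_group.groups.astype(str))
        w = basis @ lda.coef_[0]
        axis = res.cv_axes[0]
        cos = abs(w @ axis) / (np.linalg.norm(w) * np.linalg.norm(axis))
        assert cos > 1 - 1e-6

    def test_cv_scores_have_unit_within_group_variance(self, aligned_two_group):
        res = wm.cva(aligned_two_group, n_perm=0)
        g = res.groups
        pooled = 0.0
        for lbl in res.group_labels:
            s = res.cv_scores[g == lbl, 0]
            pooled += np.sum((s - s.mean()) ** 2)
        pooled /= len(g) - len(res.group_labels)
        assert pooled == pytest.approx(1.0, rel=1e-9)

    def test_distance_matrices_symmetric_zero_diagonal(self, aligned_two_group):
        res = wm.cva(aligned_two_group, n_perm=99, seed=5)
        for mat in (res.mahalanobis, res.procrustes_dist, res.perm_p):
            arr = mat.to_numpy()
            np.testing.assert_allclose(arr, arr.T)
            np.testing.assert_allclose(np.diag(arr), 0.0)

    def test_overall_f_equals_procrustes_anova_f(self, aligned_two_group):
        res = wm.cva(aligned_two_group, n_perm=0)
        an = wm.procrustes_anova(aligned_two_group, n_perm=9, seed=0)
        assert res.overall_f == pytest.approx(an.shape_f, rel=1e-12)

    def test_permutation_p_reproducible_and_never_zero(self, aligned_two_group):
        r1 = wm.cva(aligned_two_group, n_perm=199, seed=21)
        r2 = wm.cva(aligned_two_group, n_perm=199, seed=21)
        assert r1.perm_p.loc["A", "B"] == r2.perm_p.loc["A", "B"]
        assert r1.perm_p.loc["A", "B"] >= 1 / 200

    def test_procrustes_distance_entry_matches_group_means(
        self, aligned_two_group
    ):
        res = wm.cva(aligned_two_group, n_perm=0)
        d = wm.procrustes_distance(
            aligned_two_group.group_mean_shape("A"),
            aligned_two_group.group_mean_shape("B"),
        )
        assert res.procrustes_dist.loc["A", "B"] == pytest.approx(d, rel=1e-12)


def test_between_ss_helper_matches_direct_formula(rng):
    x = rng.normal(size=(30, 4))
    codes = np.repeat([0, 1, 2], 10)
    ss = _between_ss(x, codes, 3)
    grand = x.mean(axis=0)
    expected = sum(
        10 * np.sum((x[codes == j].mean(axis=0) - grand) ** 2) for j in range(3)
    )
    assert ss == pytest.approx(expected, rel=1e-12)
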