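"""PCA, CVA / Mahalanobis distances, permutation tests, correlation."""

import numpy as np
import pandas as pd
import pytest

import wingmorph as wm
from wingmorph.errors import AnalysisError


def make_groups(rng, g=3, n=15, p=5, spread=3.0):
    """Full-rank multi-group Gaussian data with distinct means."""
    means = rng.normal(scale=spread, size=(g, p))
    x = np.vstack([means[i] + rng.normal(size=(n, p)) for i in range(g)])
    labels = np.repeat([f"g{i}" for i in range(g)], n)
    return x, labels


class TestPca:
    def test_line_data_one_component(self, rng):
        t = rng.normal(size=30)
        direction = np.array([1.0, 2.0, -1.0])
        x = np.outer(t, direction)
        res = wm.pca(x)
        assert res.proportion[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction(self, rng):
        x = rng.normal(size=(12, 5))
        res = wm.pca(x)
        rebuilt = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(rebuilt, x, atol=1e-10)

    def test_eigenvalue_oracle(self, rng):
        """Eigenvalues match a dense eigendecomposition of the sample
        covariance on a 10x6 matrix."""
        x = rng.normal(size=(10, 6))
        res = wm.pca(x)
        expected = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-10)

    def test_proportions_and_score_covariance(self, rng):
        x = rng.normal(size=(20, 4))
        res = wm.pca(x)
        assert res.proportion.sum() == pytest.approx(1.0, abs=1e-12)
        cov = res.scores.T @ res.scores / (len(x) - 1)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-10)

    def test_sign_convention(self, rng):
        x = rng.normal(size=(15, 4))
        res = wm.pca(x)
        for j in range(res.loadings.shape[1]):
            i = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[i, j] > 0


class TestCva:
    def test_identical_means(self, rng):
        base = rng.normal(size=(40, 4))
        x = np.vstack([base, base])  # two groups, exactly equal distribution
        labels = ["a"] * 40 + ["b"] * 40
        res = wm.CanonicalVariates(x, labels).fit()
        assert res.mahalanobis_d.loc["a", "b"] == pytest.approx(0, abs=1e-8)
        assert res.eigenvalues[0] == pytest.approx(0, abs=1e-8)

    def test_closed_form_distance(self):
        """Means (0,0) and (2,0) with pooled covariance exactly the
        identity give D = 2, D^2 = 4."""
        a = np.sqrt(1.5)  # 4 points per group -> pooled cov = identity
        cloud = np.array([[a, 0], [-a, 0], [0, a], [0, -a]])
        x = np.vstack([cloud, cloud + [2, 0]])
        labels = ["a"] * 4 + ["b"] * 4
        res = wm.CanonicalVariates(x, labels, var_retain=1.0).fit()
        assert res.mahalanobis_d.loc["a", "b"] == pytest.approx(2.0, abs=1e-8)
        assert res.mahalanobis_d2.loc["a", "b"] == pytest.approx(4.0, abs=1e-8)

    def test_direct_quadratic_form(self, rng):
        """CVA-space distances equal (mi-mj)' W^-1 (mi-mj) computed from
        the raw full-rank data."""
        x, labels = make_groups(rng, g=4, n=20, p=6)
        res = wm.CanonicalVariates(x, labels, var_retain=1.0).fit()
        names = res.group_names
        means = {g: x[np.asarray(labels) == g].mean(axis=0) for g in names}
        n, gcount = len(x), len(names)
        sw = np.zeros((6, 6))
        for g in names:
            xg = x[np.asarray(labels) == g] - means[g]
            sw += xg.T @ xg
        w = sw / (n - gcount)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d = means[a] - means[b]
                d2 = d @ np.linalg.solve(w, d)
                assert res.mahalanobis_d2.loc[a, b] == pytest.approx(
                    d2, rel=1e-8
                )

    def test_max_nonzero_eigenvalues(self, rng):
        """At most g-1 canonical eigenvalues are reported/nonzero."""
        x, labels = make_groups(rng, g=3, n=25, p=10)
        res = wm.CanonicalVariates(x, labels).fit()
        assert len(res.eigenvalues) <= 2

    def test_affine_invariance_of_d(self, rng):
        x, labels = make_groups(rng, g=3, n=30, p=4)
        res1 = wm.CanonicalVariates(x, labels, var_retain=1.0).fit()
        t = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        res2 = wm.CanonicalVariates(x @ t + rng.normal(size=4), labels,
                                    var_retain=1.0).fit()
        np.testing.assert_allclose(
            res1.mahalanobis_d.to_numpy(), res2.mahalanobis_d.to_numpy(),
            atol=1e-8,
        )

    def test_within_group_unit_variance(self, rng):
        """Scores have pooled within-group variance 1 along each axis."""
        x, labels = make_groups(rng, g=3, n=30, p=5)
        res = wm.CanonicalVariates(x, labels, var_retain=1.0).fit()
        labels = np.asarray(labels)
        pooled = np.zeros(res.scores.shape[1])
        for g in res.group_names:
            sg = res.scores[labels == g]
            sg = sg - sg.mean(axis=0)
            pooled += (sg**2).sum(axis=0)
        pooled /= len(x) - len(res.group_names)
        np.testing.assert_allclose(pooled, 1.0, atol=1e-8)

    def test_small_group_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(AnalysisError, match="fewer than 2"):
            wm.CanonicalVariates(x, ["a", "a", "a", "a", "b"]).fit()

    def test_rank_deficient_tangent_data(self, small_gpa):
        """CVA runs on genuinely rank-deficient tangent data (2k
        variables, rank 2k-4) thanks to the PCA pre-reduction."""
        labels = small_gpa.metadata["group_label"]
        res = wm.CanonicalVariates(small_gpa.tangent, labels).fit()
        assert res.n_groups == 5  # 4 references + placebo
        assert res.n_components_retained <= small_gpa.n - 5
        d = res.mahalanobis_d
        assert (d.to_numpy() >= 0).all()
        assert np.allclose(d.to_numpy(), d.to_numpy().T)


class TestPermutation:
    def test_determinism(self, rng):
        xa = rng.normal(size=(15, 4))
        xb = rng.normal(size=(15, 4))
        p1 = wm.two_group_permutation(xa, xb, n_perm=199, seed=5)
        p2 = wm.two_group_permutation(xa, xb, n_perm=199, seed=5)
        assert p1 == p2

    def test_saturated_separation(self, rng):
        """Groups 10 pooled SDs apart give the smallest achievable p."""
        xa = rng.normal(size=(20, 3))
        xb = rng.normal(size=(20, 3)) + [10, 0, 0]
        p = wm.two_group_permutation(xa, xb, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_p_in_achievable_range(self, rng):
        xa = rng.normal(size=(10, 3))
        xb = rng.normal(size=(10, 3))
        p = wm.two_group_permutation(xa, xb, n_perm=99, seed=2)
        assert 1 / 100 <= p <= 1

    def test_pairwise_matrix(self, rng):
        x, labels = make_groups(rng, g=3, n=12, p=4, spread=4.0)
        res = wm.CanonicalVariates(x, labels).fit()
        pv = res.permutation_test(n_perm=99, seed=3)
        assert pv.shape == (3, 3)
        assert (np.diag(pv) == 1).all()
        assert (pv.to_numpy() <= 1).all() and (pv.to_numpy() >= 1 / 100).all()


class TestCorrelation:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = wm.size_covariate_correlation(-x, x)
        assert res.r == pytest.approx(-1.0)

    def test_hand_table(self):
        """Five pairs checked against the raw sum formula."""
        alt = np.array([2600.0, 2700.0, 2900.0, 3100.0, 3274.0])
        cs = np.array([7.9, 7.6, 7.8, 7.2, 7.3])
        res = wm.size_covariate_correlation(cs, alt)
        n = 5
        sx, sy = alt.sum(), cs.sum()
        sxx, syy, sxy = (alt**2).sum(), (cs**2).sum(), (alt * cs).sum()
        r_hand = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        # two-sided p from the t transform with n-2 df
        import scipy.stats

        t = r_hand * np.sqrt((n - 2) / (1 - r_hand**2))
        p_hand = 2 * scipy.stats.t.sf(abs(t), n - 2)
        assert res.pvalue == pytest.approx(p_hand, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            wm.size_covariate_correlation([1, 1, 1], [1, 2, 3])
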