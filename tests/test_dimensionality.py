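"""Correlation PCA, Camargo evenness, eigenvalue evenness, importance values."""

import numpy as np
import pandas as pd
import pytest

import grassdiv as g
from grassdiv.dimensionality import METRIC_COLUMNS, metric_matrix


def make_profile(M: np.ndarray, category: str = "intensive") -> g.DiversityProfile:
    df = pd.DataFrame(M, columns=list(METRIC_COLUMNS))
    df.insert(0, "category", category)
    df.insert(0, "plot", [f"p{i}" for i in range(len(df))])
    return g.DiversityProfile(df)


class TestCamargo:
    def test_equal_values_one(self):
        assert g.camargo_evenness([0.2, 0.2, 0.2]) == pytest.approx(1.0)

    def test_single_dominant(self):
        assert g.camargo_evenness([1.0, 0.0, 0.0]) == pytest.approx(1 / 3)

    def test_forced_arithmetic(self):
        assert g.camargo_evenness([0.6, 0.3, 0.1]) == pytest.approx(1 - (0.3 + 0.5 + 0.2) / 3)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 1, size=int(rng.integers(2, 8)))
            q = v / v.sum()
            brute = 1 - sum(abs(q[i] - q[j]) for i in range(len(q))
                            for j in range(i + 1, len(q))) / len(q)
            assert g.camargo_evenness(v) == pytest.approx(brute, rel=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(g.ValidationError):
            g.camargo_evenness([0.0, 0.0])


class TestPcaCorrelation:
    def test_uncorrelated_metrics_unit_eigenvalues(self, rng):
        M = rng.normal(size=(5000, 3))
        lam, r = g.pca_correlation(M)
        np.testing.assert_allclose(lam, [1, 1, 1], atol=0.1)
        assert lam.sum() == pytest.approx(3.0, abs=1e-9)

    def test_collinear_pair_rank_structure(self, rng):
        x = rng.normal(size=2000)
        M = np.column_stack([x, 2 * x + 5, rng.normal(size=2000)])
        lam, _ = g.pca_correlation(M)
        assert lam[0] == pytest.approx(2.0, abs=0.1)
        assert lam[2] == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_eigendecomposition(self, rng):
        M = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 3))
        lam, r = g.pca_correlation(M)
        corr = np.corrcoef(M, rowvar=False)
        lam_oracle = np.sort(np.linalg.eigvals(corr).real)[::-1]
        np.testing.assert_allclose(lam, lam_oracle, atol=1e-9)
        # loadings are metric-component correlations: column sums of r^2 = lambda
        np.testing.assert_allclose((r**2).sum(axis=0), lam, atol=1e-9)
        # and each r[m,k] equals the Pearson correlation of metric m with score k
        Z = (M - M.mean(0)) / M.std(0, ddof=1)
        corr2 = np.corrcoef(M, rowvar=False)
        w, v = np.linalg.eigh(corr2)
        order = np.argsort(w)[::-1]
        scores = Z @ v[:, order]
        for k in range(3):
            if lam[k] < 1e-10:
                continue
            for m in range(3):
                rho = np.corrcoef(M[:, m], scores[:, k])[0, 1]
                assert abs(abs(rho) - abs(r[m, k])) < 1e-8


class TestEvennessOfEigenvalues:
    def test_identity_correlation(self):
        assert g.evenness_of_eigenvalues(np.array([1.0, 1.0, 1.0])) == pytest.approx(1.0)

    def test_single_dimension(self):
        assert g.evenness_of_eigenvalues(np.array([3.0, 0.0, 0.0])) == pytest.approx(1 / 3)

    def test_collinear_fixture(self, rng):
        x = rng.normal(size=500)
        M = np.column_stack([x, 3 * x + 1, -2 * x])  # perfectly correlated metrics
        lam, _ = g.pca_correlation(M)
        assert g.evenness_of_eigenvalues(lam) == pytest.approx(1 / 3, abs=1e-9)

    def test_monotone_in_pairwise_correlation(self, rng):
        """For 2 metrics, EE decreases as |correlation| grows."""
        x = rng.normal(size=20000)
        e = rng.normal(size=20000)
        ees = []
        for rho in [0.0, 0.3, 0.6, 0.9, 0.99]:
            y = rho * x + np.sqrt(1 - rho**2) * e
            lam, _ = g.pca_correlation(np.column_stack([x, y]))
            ees.append(g.evenness_of_eigenvalues(lam))
        assert all(a > b for a, b in zip(ees, ees[1:]))


class TestImportanceValues:
    def test_uncorrelated_metrics_equal_ivs(self, rng):
        M = rng.normal(size=(5000, 3))
        lam, r = g.pca_correlation(M)
        iv = g.importance_values(lam, r)
        np.testing.assert_allclose(iv, [1 / 3] * 3, atol=0.05)

    def test_sum_to_one_and_hand_loop(self, rng):
        for _ in range(10):
            M = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3))
            lam, r = g.pca_correlation(M)
            iv = g.importance_values(lam, r)
            assert iv.sum() == pytest.approx(1.0, abs=1e-12)
            p = lam / lam.sum()
            raw = np.array([sum(p[k] * r[m, k] ** 2 for k in range(3)) for m in range(3)])
            np.testing.assert_allclose(iv, raw / raw.sum(), rtol=1e-12)

    def test_abs_r_variant_also_normalized(self, rng):
        M = rng.normal(size=(40, 3))
        lam, r = g.pca_correlation(M)
        iv = g.importance_values(lam, r, variant="abs_r")
        assert iv.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sign_indeterminacy_has_no_effect(self, rng):
        M = rng.normal(size=(60, 3))
        lam, r = g.pca_correlation(M)
        iv1 = g.importance_values(lam, r)
        iv2 = g.importance_values(lam, -r)
        np.testing.assert_allclose(iv1, iv2, rtol=1e-12)


class TestIvEvenness:
    def test_equal_ivs(self):
        assert g.iv_evenness(np.array([1 / 3, 1 / 3, 1 / 3])) == pytest.approx(1.0)

    def test_reported_style_ivs(self):
        # two metrics sharing the load, one marginal
        assert g.iv_evenness(np.array([0.04, 0.48, 0.48])) == pytest.approx(
            1 - (0.44 + 0.44 + 0.0) / 3)

    def test_single_metric(self):
        assert g.iv_evenness(np.array([1.0, 0.0, 0.0])) == pytest.approx(1 / 3)


class TestAffineInvariance:
    def test_ee_and_iv_invariant_to_metric_affine_transform(self, rng):
        M = rng.normal(size=(80, 3)) @ rng.normal(size=(3, 3))
        lam1, r1 = g.pca_correlation(M)
        M2 = M * np.array([2.0, 0.5, 10.0]) + np.array([-3.0, 7.0, 0.0])
        lam2, r2 = g.pca_correlation(M2)
        assert g.evenness_of_eigenvalues(lam1) == pytest.approx(
            g.evenness_of_eigenvalues(lam2), rel=1e-9)
        np.testing.assert_allclose(g.importance_values(lam1, r1),
                                   g.importance_values(lam2, r2), rtol=1e-9)

    def test_metric_order_invariance(self, rng):
        M = rng.normal(size=(80, 3)) @ rng.normal(size=(3, 3))
        lam1, r1 = g.pca_correlation(M)
        perm = [2, 0, 1]
        lam2, r2 = g.pca_correlation(M[:, perm])
        assert g.evenness_of_eigenvalues(lam2) == pytest.approx(
            g.evenness_of_eigenvalues(lam1), rel=1e-9)
        np.testing.assert_allclose(g.importance_values(lam2, r2),
                                   g.importance_values(lam1, r1)[perm], rtol=1e-9)


class TestMetricMatrixAndBootstrap:
    def test_metric_matrix_shape_and_order(self, mini_profile):
        M = metric_matrix(mini_profile, "intensive")
        assert M.shape == (6, 3)

    def test_absent_category_errors(self, mini_profile):
        with pytest.raises(g.ValidationError, match="no plots"):
            metric_matrix(g.DiversityProfile(
                mini_profile.table[mini_profile.table.category == "intensive"]),
                "extensive")

    def test_zero_variance_metric_named(self, rng):
        M = rng.normal(size=(10, 3))
        M[:, 1] = 5.0
        prof = make_profile(M)
        with pytest.raises(g.ValidationError, match="raoD"):
            metric_matrix(prof, "intensive")

    def test_point_estimate_only_when_no_boot(self, mini_profile):
        res = g.bootstrap_iv_evenness(mini_profile, "intensive", n_boot=0)
        assert res.IV_evenness_CI is None
        assert res.IV.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bootstrap_determinism(self, mini_profile):
        r1 = g.bootstrap_iv_evenness(mini_profile, "intensive", n_boot=49, seed=8)
        r2 = g.bootstrap_iv_evenness(mini_profile, "intensive", n_boot=49, seed=8)
        assert r1.IV_evenness_CI == r2.IV_evenness_CI

    def test_ci_brackets_reasonably(self, rng):
        M = rng.normal(size=(40, 3)) @ (np.eye(3) + 0.2 * rng.normal(size=(3, 3)))
        prof = make_profile(M)
        res = g.bootstrap_iv_evenness(prof, "intensive", n_boot=199, seed=4)
        lo, hi = res.IV_evenness_CI
        assert lo <= res.IV_evenness <= hi
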