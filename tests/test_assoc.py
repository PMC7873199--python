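"""Trait preprocessing, kinship LMM, logistic, polychoric, group tests."""

import math

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm

from amylocnv.assoc import (
    KinshipEigen,
    SeparationError,
    TraitVector,
    bonferroni_threshold,
    chi_square_test,
    dichotomize_bmi,
    heritability,
    inverse_normal,
    lmm_fit,
    logistic_fit,
    ordinal_table,
    polychoric,
    remove_outliers,
    round_sig,
    threshold_kinship,
    wilcoxon_rank_sum,
)
from amylocnv.simulate import simulate_ordinal_pair


class TestRemoveOutliers:
    def test_extreme_point_removed(self):
        x = np.concatenate([np.zeros(99), [100.0]])
        tv = remove_outliers(x)
        assert tv.n_removed == 1 and 100.0 not in tv.values

    def test_gaussian_removal_rate_matches_tail_mass(self):
        """For a standard normal, mass beyond 3 SD is 2*Phi(-3) ~ 0.27%."""
        rng = np.random.default_rng(1)
        tv = remove_outliers(rng.standard_normal(10_000))
        assert 0.001 < tv.n_removed / 10_000 < 0.006

    def test_constant_input_unchanged_with_warning(self):
        with pytest.warns(UserWarning):
            tv = remove_outliers(np.ones(10))
        assert tv.n_removed == 0 and len(tv.values) == 10

    def test_mean_sd_from_full_input_single_pass(self):
        # two symmetric outliers: both removed relative to the FULL-input SD,
        # not sequentially re-estimated
        x = np.concatenate([np.zeros(200), [50.0, -50.0]])
        assert remove_outliers(x).n_removed == 2


class TestInverseNormal:
    def test_two_point_closed_form(self):
        y = inverse_normal([5.0, 9.0]).values
        assert y == pytest.approx([-0.67448975, 0.67448975], abs=1e-8)

    def test_median_zero_for_odd_distinct(self):
        y = inverse_normal(np.arange(11.0)).values
        assert np.median(y) == pytest.approx(0.0, abs=1e-12)

    def test_rank_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=101)
        perm = rng.permutation(101)
        assert inverse_normal(x[perm]).values == pytest.approx(
            inverse_normal(x).values[perm]
        )

    def test_output_passes_normality(self):
        rng = np.random.default_rng(3)
        y = inverse_normal(rng.exponential(size=2000)).values
        assert scipy.stats.shapiro(y).pvalue > 0.01
        assert abs(y.mean()) < 1e-6 and y.std() == pytest.approx(1.0, abs=0.02)

    def test_all_tied_errors(self):
        with pytest.raises(ValueError):
            inverse_normal(np.ones(5))

    def test_blom_offset_available(self):
        y = inverse_normal([1.0, 2.0], offset="blom").values
        q = (np.array([1, 2]) - 0.375) / 2.25
        assert y == pytest.approx(scipy.stats.norm.ppf(q))


class TestThresholdKinship:
    def test_identity_unchanged(self):
        K = np.eye(4) * 0.5
        assert np.array_equal(threshold_kinship(K), K)

    def test_below_threshold_zeroed_boundary_kept(self):
        K = np.eye(3) * 0.5
        K[0, 1] = K[1, 0] = 0.04
        K[1, 2] = K[2, 1] = 0.05
        out = threshold_kinship(K, 0.05)
        assert out[0, 1] == 0.0 and out[1, 2] == 0.05
        assert np.array_equal(out, out.T)

    def test_asymmetric_rejected(self):
        K = np.eye(3)
        K[0, 1] = 0.2
        with pytest.raises(ValueError):
            threshold_kinship(K)


class TestLMM:
    def _design(self, n, rng):
        X = np.column_stack([rng.integers(0, 2, n).astype(float), rng.normal(size=n)])
        x = rng.normal(size=n)
        return X, x

    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(4)
        n = 300
        X, x = self._design(n, rng)
        y = 0.5 * x + rng.normal(size=n)
        fit = lmm_fit(y, X, np.eye(n) * 0.5, predictor=x)
        ols = sm.OLS(y, sm.add_constant(np.column_stack([X, x]))).fit()
        assert fit.assoc.beta == pytest.approx(ols.params[-1], abs=1e-6)
        assert fit.assoc.se == pytest.approx(ols.bse[-1], abs=1e-6)

    def test_wald_p_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(5)
        n = 300
        X, x = self._design(n, rng)
        K = np.eye(n) * 0.5
        for i in range(0, n - 3, 4):  # sib pairs
            K[i, i + 1] = K[i + 1, i] = 0.25
        y = 0.1 * x + rng.normal(size=n)
        f1 = lmm_fit(y, X, K, predictor=x)
        X2 = X.copy()
        X2[:, 1] *= 1000.0
        f2 = lmm_fit(y, X2, K, predictor=x)
        assert f1.assoc.p == pytest.approx(f2.assoc.p, abs=1e-8)
        assert f1.assoc.beta == pytest.approx(f2.assoc.beta, rel=1e-6)

    def test_non_psd_kinship_suggests_jitter(self):
        K = np.eye(3) * 0.5
        K[0, 1] = K[1, 0] = 2.0
        with pytest.raises(ValueError, match="jitter"):
            lmm_fit(np.zeros(3), None, K, max_iter=10)

    def test_block_eigen_matches_dense(self):
        rng = np.random.default_rng(6)
        n = 40
        K = np.eye(n) * 0.5
        for i in range(0, n, 4):
            K[i : i + 4, i : i + 4] = 0.25
            np.fill_diagonal(K[i : i + 4, i : i + 4], 0.5)
        eig = KinshipEigen(2 * K)
        assert np.sort(eig.eigenvalues) == pytest.approx(
            np.sort(np.linalg.eigvalsh(2 * K)), abs=1e-10
        )
        v = rng.normal(size=n)
        assert np.linalg.norm(eig.rotate(v)) == pytest.approx(np.linalg.norm(v))

    def test_heritability_bounds(self):
        rng = np.random.default_rng(7)
        n = 200
        y = rng.normal(size=n)
        est = heritability(y, None, np.eye(n) * 0.5)
        assert 0.0 <= est.h2 <= 1.0
        assert est.sigma2_g >= 0 and est.sigma2_e >= 0


class TestBonferroni:
    def test_printed_threshold(self):
        thr = bonferroni_threshold(0.05, 3, 2)
        assert thr == 0.05 / 6
        assert round_sig(thr, 3) == pytest.approx(8.33e-3)

    @pytest.mark.parametrize(
        "alpha,a,b,expected", [(0.05, 1, 1, 0.05), (0.01, 2, 5, 0.001)]
    )
    def test_values(self, alpha, a, b, expected):
        assert bonferroni_threshold(alpha, a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0, 2)


class TestLogistic:
    def test_null_or_near_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.integers(2, 15, n).astype(float)
        y = rng.integers(0, 2, n)
        res = logistic_fit(y, x)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.03)
        assert res.ci_low < 1.0 < res.ci_high

    def test_bmi_dichotomization(self):
        y, mask = dichotomize_bmi(np.array([31.0, 24.0, 27.0]))
        assert list(mask) == [True, True, False]
        assert list(y) == [1, 0]

    def test_separation_detected(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            logistic_fit(y, x)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.arange(10.0))


class TestPolychoric:
    def test_independence_near_zero(self):
        tab = simulate_ordinal_pair(0.0, 5000, rng=9)
        assert abs(polychoric(tab).rho) < 0.04

    def test_ml_matches_grid_search_on_toy_table(self):
        """The bounded ML optimum agrees with a 1e-3-step brute-force grid."""
        tab = np.array([[20, 10, 5], [8, 25, 10], [3, 9, 30]])
        res = polychoric(tab)
        a, b = res.row_thresholds, res.col_thresholds
        from amylocnv.assoc import _bvn_rect_probs

        grid = np.arange(-0.995, 0.996, 0.001)
        lls = [np.sum(tab * np.log(_bvn_rect_probs(r, a, b))) for r in grid]
        assert res.rho == pytest.approx(grid[int(np.argmax(lls))], abs=2e-3)

    def test_empty_margin_collapsed(self):
        tab = np.array([[10, 0, 5], [7, 0, 9]])
        with pytest.warns(UserWarning):
            res = polychoric(tab)
        assert -1 < res.rho < 1

    def test_ordinal_table_shape(self):
        t = ordinal_table([1, 1, 2, 3], [0, 1, 0, 1])
        assert t.shape == (3, 2) and t.sum() == 4


class TestGroupTests:
    def test_exact_rank_sum_enumeration(self):
        # fully separated groups of 3: P = 2/C(6,3) = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [11, 12, 13]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_null_p_values_uniform(self):
        """Permuted labels on one distribution: P-values are U(0,1)."""
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(400):
            x = rng.normal(size=100)
            ps.append(wilcoxon_rank_sum(x[:50], x[50:], method="asymptotic"))
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_chi_square(self):
        p = chi_square_test([[50, 50], [50, 50]])
        assert p == pytest.approx(1.0)
        assert chi_square_test([[90, 10], [10, 90]]) < 1e-10
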