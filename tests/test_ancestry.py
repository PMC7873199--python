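"""HWE exact test, variant QC, LD pruning, PCA, ancestry, sliding windows."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from amylocnv.ancestry import (
    GenotypeMatrix,
    WindowSpec,
    assign_ancestry,
    group_centroids,
    hwe_exact_test,
    ld_prune,
    ld_violations,
    pca,
    sliding_windows,
    variant_qc,
    windowed_association,
)
from amylocnv.simulate import simulate_genotype_matrix


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent brute-force oracle: direct log-factorial probability of
    every admissible heterozygote count."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    if min(n_a, n_A) == 0:
        return 1.0

    def logp(h):
        # un-normalized log P(h | allele counts); constants cancel on softmax
        aa = (n_a - h) // 2
        AA = n - h - aa
        return (
            -math.lgamma(AA + 1) - math.lgamma(h + 1) - math.lgamma(aa + 1)
            + h * math.log(2)
        )

    hets = [h for h in range(n_a % 2, min(n_a, n_A) + 1, 2)]
    lps = np.array([logp(h) for h in hets])
    ps = np.exp(lps - lps.max())
    ps /= ps.sum()
    obs = ps[hets.index(n_Aa)]
    return float(ps[ps <= obs * (1 + 1e-12)].sum())


def make_matrix(dosages, pos=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages,
        np.array([f"s{i}" for i in range(n)]),
        np.array([f"v{j}" for j in range(m)]),
        np.array(chrom if chrom is not None else ["1"] * m),
        np.array(pos if pos is not None else np.arange(m) * 1000),
    )


class TestHWE:
    def test_monomorphic_convention(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_all_heterozygous(self):
        for n in (4, 11, 40):
            assert hwe_exact_test(0, n, 0) == pytest.approx(hwe_oracle(0, n, 0), abs=1e-12)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            n = int(rng.integers(2, 200))
            n_AA = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_AA + 1))
            n_aa = n - n_AA - n_Aa
            assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)


class TestVariantQC:
    def test_toy_matrix_one_failure_per_criterion(self):
        rng = np.random.default_rng(22)
        n = 200
        good = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        low_maf = np.zeros((n, 1)); low_maf[0] = 1  # MAF 0.0025
        missing = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        missing[: int(0.15 * n)] = np.nan  # call rate 0.85
        hwe_bad = np.ones((n, 1))  # all heterozygous
        good2 = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        G = make_matrix(np.hstack([good, low_maf, missing, hwe_bad, good2]))
        out, rep = variant_qc(G)
        assert out.n_variants == 2
        assert (rep.n_fail_maf, rep.n_fail_call_rate, rep.n_fail_hwe) >= (1, 1, 1)
        assert list(out.variant_ids) == ["v0", "v4"]

    def test_all_removed_errors(self):
        G = make_matrix(np.zeros((50, 2)))
        with pytest.raises(ValueError):
            variant_qc(G)


class TestLDPrune:
    def test_single_variant_kept(self):
        rng = np.random.default_rng(23)
        G = make_matrix(rng.binomial(2, 0.4, size=(50, 1)).astype(float))
        assert list(ld_prune(G)) == [0]

    def test_duplicated_variant_dropped(self):
        rng = np.random.default_rng(24)
        v = rng.binomial(2, 0.4, size=(100, 1)).astype(float)
        G = make_matrix(np.hstack([v, v]))
        assert len(ld_prune(G)) == 1

    def test_three_variant_toy(self):
        """Pairwise r2 ~ {high, low, low}: exactly one of the correlated
        pair is removed."""
        rng = np.random.default_rng(25)
        a = rng.binomial(2, 0.5, size=300).astype(float)
        b = a.copy()
        flip = rng.random(300) < 0.05
        b[flip] = rng.binomial(2, 0.5, size=int(flip.sum()))
        c = rng.binomial(2, 0.5, size=300).astype(float)
        G = make_matrix(np.column_stack([a, b, c]))
        kept = ld_prune(G, r2_max=0.05)
        assert len(kept) == 2 and 2 in kept

    def test_unsorted_positions_rejected(self):
        rng = np.random.default_rng(26)
        G = make_matrix(
            rng.binomial(2, 0.4, size=(50, 3)).astype(float), pos=[3000, 1000, 2000]
        )
        with pytest.raises(ValueError, match="unsorted"):
            ld_prune(G)

    def test_postcondition_no_violations_on_ld_matrix(self):
        G, _ = simulate_genotype_matrix(
            {"pop1": 120}, m_variants=200, fst=0.0, ld_rho=0.9, rng=27
        )
        kept = ld_prune(G, r2_max=0.05)
        assert ld_violations(G, kept, r2_max=0.05) == 0
        assert 0 < len(kept) < G.n_variants


class TestPCA:
    def test_two_population_separation(self):
        G, labels = simulate_genotype_matrix(
            {"pop1": 100, "pop2": 100}, m_variants=500, fst=0.05, rng=28
        )
        res = pca(G, 2)
        pc1 = res.coords[:, 0]
        mid = (pc1[labels == "pop1"].mean() + pc1[labels == "pop2"].mean()) / 2
        side = pc1 > mid
        acc = max((side == (labels == "pop1")).mean(), (side == (labels == "pop2")).mean())
        assert acc >= 0.95

    def test_identical_samples_degenerate(self):
        # identical samples leave every variant constant: nothing to decompose
        row = np.tile(np.array([0.0, 1.0, 2.0, 1.0]), (10, 1))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no variable variants"):
                pca(make_matrix(row))

    def test_orthogonality_and_variance_accounting(self):
        rng = np.random.default_rng(29)
        G = make_matrix(rng.binomial(2, 0.4, size=(60, 40)).astype(float))
        res = pca(G, 10)
        crossed = res.coords.T @ res.coords
        off = crossed - np.diag(np.diag(crossed))
        assert np.abs(off).max() < 1e-8
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-10)
        # total standardized variance = number of retained variants
        assert ev.sum() == pytest.approx(len(res.kept_variants), abs=1e-6)


class TestAssignAncestry:
    def test_sample_at_centroid(self):
        cents = {"A": np.array([0.0, 0.0]), "B": np.array([10.0, 0.0])}
        out = assign_ancestry(np.array([[0.0, 0.0]]), cents)
        assert out[0].group == "A"

    def test_equidistant_is_admixed(self):
        cents = {"A": np.array([0.0, 0.0]), "B": np.array([10.0, 0.0])}
        out = assign_ancestry(np.array([[5.0, 0.0]]), cents)
        assert out[0].group == "Admixed"

    def test_missing_coords_rejected(self):
        cents = {"A": np.zeros(2), "B": np.ones(2)}
        with pytest.raises(ValueError):
            assign_ancestry(np.array([[np.nan, 0.0]]), cents)

    def test_three_group_cohort_with_admixture(self):
        """10% admixed draws between the first two groups: recall >= 80%
        for admixed samples, and pure samples rarely mislabelled admixed."""
        G, labels = simulate_genotype_matrix(
            {"pop1": 150, "pop2": 150, "pop3": 100},
            m_variants=600,
            fst=0.08,
            admixed_frac=0.2,  # of pop1 draws -> ~30 admixed
            rng=30,
        )
        res = pca(G, 2)
        pure = labels != "Admixed"
        cents = group_centroids(res.coords[pure], labels[pure])
        calls = np.array(
            [a.group for a in assign_ancestry(res.coords, cents)]
        )
        admixed_recall = (calls[~pure] == "Admixed").mean()
        pure_acc = (calls[pure] == labels[pure]).mean()
        assert admixed_recall >= 0.8
        assert pure_acc >= 0.8


class TestSlidingWindows:
    @pytest.mark.parametrize("n,expected", [(1518, 10), (948, 3), (750, 1)])
    def test_printed_window_counts(self, n, expected):
        wins = sliding_windows(n, WindowSpec(750, 85))
        assert len(wins) == expected
        assert all(len(w) == 750 for w in wins)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            sliding_windows(700, WindowSpec(750, 85))

    def test_coverage_and_overlap_structure(self):
        wins = sliding_windows(1518, WindowSpec(750, 85))
        starts = [w[0] for w in wins]
        assert starts == [85 * k for k in range(10)]
        covered = np.unique(np.concatenate(wins))
        assert covered[0] == 0 and covered[-1] == 85 * 9 + 749

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(100, 0)


class TestWindowedAssociation:
    def test_single_window_equals_whole_sample_fit(self):
        rng = np.random.default_rng(31)
        n = 120
        pc1 = rng.normal(size=n)
        cn = rng.integers(2, 15, n).astype(float)
        cov = rng.normal(size=(n, 1))
        trait = -0.05 * cn + cov[:, 0] * 0.3 + rng.normal(size=n)
        res = windowed_association(
            pc1, trait, cn, cov, WindowSpec(n, n), within_window_transform=False
        )
        assert len(res) == 1
        X = np.column_stack([np.ones(n), cn, cov])
        fit = sm.OLS(trait, X).fit()
        assert res.loc[0, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
        assert res.loc[0, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constant_cn_window_flagged(self):
        rng = np.random.default_rng(32)
        n = 60
        res = windowed_association(
            rng.normal(size=n), rng.normal(size=n), np.full(n, 6.0), None,
            WindowSpec(n, n),
        )
        assert res.loc[0, "flag"] == "constant_cn" and np.isnan(res.loc[0, "beta"])

    def test_flat_effect_shows_no_trend(self):
        """Constant true beta along PC1: the window-index/beta rank
        correlation is not significant."""
        rng = np.random.default_rng(33)
        n = 900
        pc1 = rng.normal(size=n)
        cn = rng.integers(2, 15, n).astype(float)
        trait = -0.05 * cn + rng.normal(size=n)
        res = windowed_association(pc1, trait, cn, None, WindowSpec(300, 75))
        import scipy.stats

        rho, p = scipy.stats.spearmanr(res["window"], res["beta"])
        assert p > 0.05

    def test_ramping_effect_detected(self):
        """Effect size ramping along PC1 produces a detectable monotone
        trend in per-window estimates."""
        rng = np.random.default_rng(34)
        n = 1200
        pc1 = np.sort(rng.normal(size=n))
        slope = np.linspace(0.0, -0.25, n)  # beta ramps from 0 to -0.25
        cn = rng.integers(2, 15, n).astype(float)
        trait = slope * cn + 0.5 * rng.normal(size=n)
        res = windowed_association(pc1, trait, cn, None, WindowSpec(300, 100))
        import scipy.stats

        rho, p = scipy.stats.spearmanr(res["window"], res["beta"])
        assert rho < 0 and p < 0.05
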