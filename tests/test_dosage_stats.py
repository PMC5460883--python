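import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom, kstest

from covhmm.coverage_io import CoverageMatrix, ReferenceSummary
from covhmm.dosage_stats import (
    ResampleConfig,
    SnpSiteCounts,
    chi2_proportion,
    filter_ase_controls,
    fisher_allele_test,
    mean_fold_change,
    resample_tissue_bias,
    wilcoxon_rank_sum,
)


def cov_with_ref(sample_values, mu_values):
    n = len(sample_values)
    cov = CoverageMatrix(
        "chr1", np.arange(1, n + 1), ["s"], np.asarray(sample_values, float)
    )
    ref = ReferenceSummary(np.asarray(mu_values, float), np.zeros(n), 3)
    return cov, ref


class TestMeanFoldChange:
    def test_reference_floored_at_one_read(self):
        cov, ref = cov_with_ref([10.0] * 100, [0.4] * 100)
        rec = mean_fold_change(cov, "s", ref, (0, 100))
        assert rec.fold_change == pytest.approx(10.0)
        assert rec.ref_mean == 1.0

    def test_no_change_is_unity(self):
        cov, ref = cov_with_ref([20.0] * 50, [20.0] * 50)
        assert mean_fold_change(cov, "s", ref, (0, 50)).fold_change == pytest.approx(1.0)

    def test_threefold(self):
        cov, ref = cov_with_ref([30.0] * 50, [10.0] * 50)
        assert mean_fold_change(cov, "s", ref, (0, 50)).fold_change == pytest.approx(3.0)

    def test_segment_outside_track_errors(self):
        cov, ref = cov_with_ref([1.0], [1.0])
        with pytest.raises(ValueError):
            mean_fold_change(cov, "s", ref, (500, 600))

    def test_rescaling_invariance_above_floor(self):
        rng = np.random.default_rng(1)
        sample = rng.uniform(5, 50, 100)
        mu = rng.uniform(2, 40, 100)
        cov1, ref1 = cov_with_ref(sample, mu)
        cov3, ref3 = cov_with_ref(3 * sample, 3 * mu)
        fc1 = mean_fold_change(cov1, "s", ref1, (0, 100)).fold_change
        fc3 = mean_fold_change(cov3, "s", ref3, (0, 100)).fold_change
        assert fc1 == pytest.approx(fc3)


def site(dna_ref, dna_alt, rna_ref, rna_alt):
    return SnpSiteCounts("chr1", 100, "s1", dna_ref, dna_alt, rna_ref, rna_alt)


def hypergeom_two_sided(a, b, c, d):
    """Enumerate the exact conditional null over all tables with the margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {x: hypergeom.pmf(x, n, col1, row1) for x in support}
    return float(sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-9)))


class TestFisherAlleleTest:
    def test_identical_proportions(self):
        assert fisher_allele_test(site(50, 50, 50, 50)) == pytest.approx(1.0)

    def test_strong_imbalance_matches_enumeration(self):
        p = fisher_allele_test(site(50, 50, 90, 10))
        assert p < 0.05
        assert p == pytest.approx(hypergeom_two_sided(50, 50, 90, 10), rel=1e-8)

    def test_low_coverage_site_skipped(self):
        assert fisher_allele_test(site(5, 4, 50, 50)) is None
        assert fisher_allele_test(site(50, 50, 5, 4)) is None

    def test_zero_margin_degenerate(self):
        assert fisher_allele_test(site(60, 0, 55, 0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(12, 8, 4, 16), (30, 5, 20, 15), (10, 10, 10, 10)])
    def test_matches_full_enumeration(self, table):
        p = fisher_allele_test(site(*table))
        assert p == pytest.approx(hypergeom_two_sided(*table), rel=1e-8)


class TestFilterAseControls:
    p_values = {
        ("chr1", 1): {"s1": 0.001, "s2": 0.8},   # significant only in carrier
        ("chr1", 2): {"s1": 0.001, "s2": 0.01},  # also significant in non-carrier
        ("chr1", 3): {"s1": 0.5, "s2": 0.6},     # significant nowhere
    }
    carriers = {k: {"s1"} for k in p_values}

    def test_retains_carrier_only_signals(self):
        kept = filter_ase_controls(list(self.p_values), self.p_values, self.carriers)
        assert kept == [("chr1", 1)]

    def test_none_pvalues_ignored(self):
        pv = {("chr1", 1): {"s1": 0.001, "s2": None}}
        kept = filter_ase_controls([("chr1", 1)], pv, {("chr1", 1): {"s1"}})
        assert kept == [("chr1", 1)]


class TestWilcoxonRankSum:
    def test_minimal_statistic(self):
        w, _ = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 0.0

    def test_maximal_statistic(self):
        w, _ = wilcoxon_rank_sum([3, 4], [1, 2])
        assert w == 4.0  # n*m

    def test_exact_p_matches_permutation_enumeration(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        w_obs, p = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        stats = []
        for idx in itertools.combinations(range(8), 4):
            stats.append(ranks[list(idx)].sum() - 4 * 5 / 2)
        stats = np.asarray(stats)
        # two-sided: double the smaller tail of the permutation distribution
        mean = stats.mean()
        tail = min(
            np.mean(stats >= w_obs) if w_obs >= mean else np.mean(stats <= w_obs), 0.5
        )
        assert p == pytest.approx(min(1.0, 2 * tail), rel=1e-9)

    def test_statistic_bounded(self, rng):
        for _ in range(20):
            n, m = rng.integers(1, 10, 2)
            w, _ = wilcoxon_rank_sum(rng.normal(size=n), rng.normal(size=m))
            assert 0 <= w <= n * m

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestChi2Proportion:
    def test_equal_proportions_zero(self):
        stat, p = chi2_proportion(10, 100, 10, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with a=10,b=90,c=20,d=80
        stat, _ = chi2_proportion(10, 100, 20, 100)
        expected = 200 * (10 * 80 - 90 * 20) ** 2 / (100 * 100 * 30 * 170)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(3.9216, abs=1e-3)

    def test_complete_separation(self):
        stat, _ = chi2_proportion(10, 10, 0, 10)
        assert stat == pytest.approx(20.0)

    def test_degenerate_table_errors(self):
        with pytest.raises(ValueError):
            chi2_proportion(0, 10, 0, 10)


class TestResampleTissueBias:
    universe = [True] * 50 + [False] * 450

    def test_deterministic_under_fixed_seed(self):
        cfg = ResampleConfig(replicates=2000, seed=11)
        p1 = resample_tissue_bias(12, self.universe, 40, cfg)
        p2 = resample_tissue_bias(12, self.universe, 40, cfg)
        assert p1 == p2

    def test_extreme_excess_hits_resolution_floor(self):
        cfg = ResampleConfig(replicates=10_000, seed=3)
        p = resample_tissue_bias(40, self.universe, 40, cfg)
        assert p == pytest.approx(1 / 10_001)

    def test_zero_observed_excess_is_near_one(self):
        cfg = ResampleConfig(replicates=2000, seed=5)
        assert resample_tissue_bias(0, self.universe, 40, cfg) > 0.95

    def test_deficit_direction(self):
        cfg = ResampleConfig(replicates=2000, seed=5)
        p = resample_tissue_bias(0, self.universe, 40, cfg, direction="deficit")
        assert p < 0.05

    def test_null_p_values_approximately_uniform(self, rng):
        # observed counts drawn from the same null the resampler simulates;
        # a large draw size keeps the p-value granularity well below the
        # tolerance on the KS statistic
        labels = np.zeros(4000, dtype=bool)
        labels[:2000] = True
        null_obs = rng.hypergeometric(2000, 2000, 800, size=2000)
        pvals = [
            resample_tissue_bias(
                int(obs), labels, 800, ResampleConfig(replicates=1000, seed=1000 + i)
            )
            for i, obs in enumerate(null_obs)
        ]
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.05
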