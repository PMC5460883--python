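import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from covhmm.block_classify import (
    ExpressionBlock,
    background_rate,
    call_blocks,
    classify_gene_regions,
    detect_de_novo,
    enrichment_binomial,
)
from covhmm.coverage_io import Gene, ReferenceSummary
from covhmm.hmm import DOWN, STABLE, UP


def brute_force_blocks(positions, states, min_len):
    """Reference run-length scan: grow runs site by site."""
    runs = []
    cur = None
    for p, s in zip(positions, states):
        if cur and s == cur[2] and p == cur[1] + 1:
            cur[1] = p
        else:
            if cur:
                runs.append(cur)
            cur = [p, p, s]
    if cur:
        runs.append(cur)
    return [
        (r[0] - 1, r[1], r[2])
        for r in runs
        if r[2] != STABLE and r[1] - r[0] + 1 >= min_len
    ]


class TestCallBlocks:
    def test_fifty_contiguous_sites_form_block(self):
        pos = np.arange(100, 150)
        blocks = call_blocks(pos, np.full(50, UP))
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start, b.end, b.length, b.state) == (99, 149, 50, UP)

    def test_forty_nine_sites_below_threshold(self):
        assert call_blocks(np.arange(1, 50), np.full(49, UP)) == []

    def test_single_interrupting_site_splits_run(self):
        states = np.full(116, UP)
        states[60] = STABLE
        blocks = call_blocks(np.arange(1, 117), states)
        assert [b.length for b in blocks] == [60, 55]

    def test_positional_gap_splits_run(self):
        # 60 up sites but a 1-bp hole in the site track after the 30th
        pos = np.concatenate([np.arange(1, 31), np.arange(32, 62)])
        assert call_blocks(pos, np.full(60, UP)) == []

    def test_down_blocks_called_too(self):
        blocks = call_blocks(np.arange(1, 61), np.full(60, DOWN))
        assert blocks[0].state == DOWN

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 200))
    def test_matches_run_length_scan(self, seed, n):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 2 * n + 1), size=n, replace=False))
        states = rng.integers(0, 3, size=n)
        got = [(b.start, b.end, b.state) for b in call_blocks(pos, states, min_len=5)]
        assert got == brute_force_blocks(pos, states, 5)


def _gene(exons, start=None, end=None, strand="+", gene_id="g", chrom="chr1"):
    start = exons[0][0] if start is None else start
    end = exons[-1][1] if end is None else end
    return Gene(gene_id, chrom, strand, start, end, exons=list(exons))


class TestClassifyGeneRegions:
    def test_majority_exonic_coverage_is_upregulated(self):
        g = _gene([(0, 300)])
        blocks = [ExpressionBlock("chr1", 0, 160, UP)]
        (call,) = classify_gene_regions(blocks, [g])
        assert call.fraction == pytest.approx(160 / 300)
        assert call.upregulated

    def test_below_half_not_upregulated(self):
        g = _gene([(0, 300)])
        blocks = [ExpressionBlock("chr1", 0, 149, UP)]
        (call,) = classify_gene_regions(blocks, [g])
        assert not call.upregulated

    def test_exactly_half_is_upregulated(self):
        g = _gene([(0, 300)])
        (call,) = classify_gene_regions([ExpressionBlock("chr1", 0, 150, UP)], [g])
        assert call.upregulated

    def test_gene_outside_region_excluded(self):
        g = _gene([(0, 300)])
        calls = classify_gene_regions([], [g], regions={"g": (1000, 2000)})
        assert calls == []

    def test_region_restricts_to_duplicated_segment(self):
        g = _gene([(0, 400)])
        blocks = [ExpressionBlock("chr1", 200, 400, UP)]
        (call,) = classify_gene_regions(blocks, [g], regions={"g": (200, 400)})
        assert call.fraction == 1.0

    def test_invariant_to_exon_splitting(self):
        blocks = [ExpressionBlock("chr1", 50, 260, UP)]
        whole = _gene([(0, 300)])
        split = _gene([(0, 120), (120, 200), (200, 300)], start=0, end=300)
        (a,) = classify_gene_regions(blocks, [whole])
        (b,) = classify_gene_regions(blocks, [split])
        assert a.fraction == pytest.approx(b.fraction)
        assert a.exonic_bp == b.exonic_bp


class TestDetectDeNovo:
    positions = np.arange(1, 2001)

    def _ref(self, mu_value=0.5, spike_at=None):
        mu = np.full(2000, mu_value)
        if spike_at is not None:
            mu[spike_at] = 5.0
        return ReferenceSummary(mu, np.zeros(2000), 3)

    def _block(self, start=500, end=750):
        return ExpressionBlock("chr1", start, end, UP)

    def test_qualifying_block_called(self):
        calls = detect_de_novo(
            [self._block()], [], [("chr1", 400, 900)], self._ref(), self.positions
        )
        assert len(calls) == 1
        assert calls[0].dup_overlap_bp == 250

    def test_reference_coverage_spike_rejects(self):
        calls = detect_de_novo(
            [self._block()], [], [("chr1", 400, 900)],
            self._ref(spike_at=600), self.positions,
        )
        assert calls == []

    def test_short_duplication_overlap_rejects(self):
        # 250 bp block but only 180 bp inside the duplication
        calls = detect_de_novo(
            [self._block()], [], [("chr1", 570, 750)], self._ref(), self.positions
        )
        assert calls == []

    def test_exon_overlap_rejects(self):
        g = _gene([(700, 800)])
        calls = detect_de_novo(
            [self._block()], [g], [("chr1", 400, 900)], self._ref(), self.positions
        )
        assert calls == []

    def test_monotone_in_thresholds(self):
        blocks = [self._block(), self._block(1000, 1300)]
        args = (blocks, [], [("chr1", 400, 1400)], self._ref(1.5), self.positions)
        base = detect_de_novo(*args, max_ref_coverage=2.0, min_dup_overlap=200)
        looser = detect_de_novo(*args, max_ref_coverage=3.0, min_dup_overlap=100)
        got = {(c.start, c.end) for c in base}
        assert got <= {(c.start, c.end) for c in looser}


class TestBackgroundRate:
    def test_all_stable_is_zero(self):
        assert background_rate(np.full(100, STABLE)) == 0.0

    def test_counting(self):
        states = np.full(200, STABLE)
        states[:10] = UP
        assert background_rate(states) == pytest.approx(0.05)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            background_rate(np.array([]))


def minlike_binomial_p(k, n, p0):
    """Two-sided exact binomial by summing outcomes no more likely than k."""
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-10)].sum())


class TestEnrichmentBinomial:
    def test_trivial_single_trial(self):
        assert enrichment_binomial(0, 1, 0.0526).p_value == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(1, 500), st.integers(0, 2**31 - 1))
    def test_matches_pmf_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.01, 0.99))
        res = enrichment_binomial(k, n, p0)
        assert res.p_value == pytest.approx(minlike_binomial_p(k, n, p0), rel=1e-9)

    def test_one_sided_greater(self):
        res = enrichment_binomial(24, 76, 0.0526, alternative="greater")
        assert res.p_value == pytest.approx(
            float(binom.sf(23, 76, 0.0526)), rel=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            enrichment_binomial(5, 3, 0.1)
        with pytest.raises(ValueError):
            enrichment_binomial(1, 3, 0.0)
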