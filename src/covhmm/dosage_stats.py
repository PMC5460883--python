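"""Fold-change summaries and dosage/bias statistics.

Covers the auxiliary statistics around the HMM: mean fold change of a gene
segment in a sample strain versus the reference (with the reference
denominator floored at one read per site), Fisher exact tests for
allele-specific expression of duplicate copies at heterozygous SNPs,
Wilcoxon rank-sum comparisons, the 1-df chi-squared proportion test, and
the resampling test for tissue-biased duplication of genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu

from .coverage_io import CoverageMatrix, ReferenceSummary

__all__ = [
    "FoldChangeRecord",
    "SnpSiteCounts",
    "ResampleConfig",
    "mean_fold_change",
    "fisher_allele_test",
    "filter_ase_controls",
    "wilcoxon_rank_sum",
    "chi2_proportion",
    "resample_tissue_bias",
    "read_snp_counts_tsv",
]

MIN_SNP_READS = 10


@dataclass
class FoldChangeRecord:
    segment_id: str
    strain: str
    tissue: str
    sample_mean: float
    ref_mean: float  # after flooring
    fold_change: float


@dataclass(frozen=True)
class SnpSiteCounts:
    """Ref/alt read counts at one heterozygous site, DNA and RNA libraries."""

    chrom: str
    pos: int
    strain: str
    dna_ref: int
    dna_alt: int
    rna_ref: int
    rna_alt: int
    tissue: str = ""

    @property
    def dna_total(self) -> int:
        return self.dna_ref + self.dna_alt

    @property
    def rna_total(self) -> int:
        return self.rna_ref + self.rna_alt


@dataclass
class ResampleConfig:
    replicates: int = 10_000
    seed: int = 0


def mean_fold_change(
    sample: CoverageMatrix,
    sample_name: str,
    ref: ReferenceSummary,
    segment: tuple[int, int],
    segment_id: str = "",
    strain: str = "",
    tissue: str = "",
    floor: float = 1.0,
    per_site_floor: bool = False,
) -> FoldChangeRecord:
    """Mean fold change of a segment: sample mean over floored reference mean.

    ``segment`` is half-open on the chromosome of ``sample``; the reference
    summary is aligned site-wise with it. The denominator is the mean of
    the per-site reference means floored at one read (``per_site_floor``
    applies the floor per site instead, a stricter sensitivity variant).
    """
    lo, hi = segment
    mask = (sample.positions >= lo + 1) & (sample.positions <= hi)
    if not mask.any():
        raise ValueError(f"segment [{lo},{hi}) outside coverage track")
    s_mean = float(sample.column(sample_name)[mask].mean())
    mu = ref.mu[mask]
    if per_site_floor:
        r_mean = float(np.maximum(mu, floor).mean())
    else:
        r_mean = max(float(mu.mean()), floor)
    return FoldChangeRecord(
        segment_id=segment_id or f"{sample.chrom}:{lo}-{hi}",
        strain=strain or sample_name,
        tissue=tissue,
        sample_mean=s_mean,
        ref_mean=r_mean,
        fold_change=s_mean / r_mean,
    )


def fisher_allele_test(site: SnpSiteCounts, min_reads: int = MIN_SNP_READS) -> float | None:
    """Two-sided Fisher exact test of DNA vs RNA ref/alt counts at one SNP.

    Returns None (site skipped) when either library has fewer than
    ``min_reads`` reads at the site. A zero margin gives p = 1.
    """
    if site.dna_total < min_reads or site.rna_total < min_reads:
        return None
    table = [[site.dna_ref, site.dna_alt], [site.rna_ref, site.rna_alt]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def filter_ase_controls(
    candidates: Iterable[tuple],
    p_values: dict[tuple, dict[str, float]],
    carrier_map: dict[tuple, set[str]],
    alpha: float = 0.05,
) -> list[tuple]:
    """Drop candidate ASE sites that are also significant in non-carriers.

    ``candidates`` are site keys (e.g. (chrom, pos)); ``p_values`` maps a
    site key to per-strain Fisher p-values; ``carrier_map`` maps a site key
    to the strains carrying the duplication. A site significant in any
    strain that lacks the duplication reflects ordinary allele-specific
    expression, not dosage asymmetry across copies, and is removed.
    """
    kept = []
    for site in candidates:
        per_strain = p_values.get(site, {})
        carriers = carrier_map.get(site, set())
        sig_in_carrier = any(
            p is not None and p < alpha
            for strain, p in per_strain.items()
            if strain in carriers
        )
        sig_in_noncarrier = any(
            p is not None and p < alpha
            for strain, p in per_strain.items()
            if strain not in carriers
        )
        if sig_in_carrier and not sig_in_noncarrier:
            kept.append(site)
    return kept


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test; W is the rank sum of x minus its minimum.

    That convention (equal to the Mann-Whitney U of x) matches R's
    ``wilcox.test`` W. Exact p for small samples without ties, normal
    approximation with tie correction otherwise; two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chi2_proportion(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("need n1, n2 > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: an expected cell is zero")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def resample_tissue_bias(
    observed: int,
    universe_labels: Sequence[bool],
    set_size: int,
    config: ResampleConfig | None = None,
    direction: str = "excess",
) -> float:
    """Resampling test for tissue-biased genes among duplicated genes.

    Draws ``set_size`` genes without replacement from the universe
    ``config.replicates`` times and counts biased genes per draw. The
    one-sided empirical p uses the add-one correction
    p = (1 + #{count >= observed}) / (1 + replicates) for an excess
    (``direction="deficit"`` tests with <=).
    """
    config = config or ResampleConfig()
    labels = np.asarray(universe_labels, dtype=bool)
    if set_size > labels.size:
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(config.seed)
    # biased count in a without-replacement draw of exchangeable labels is
    # exactly hypergeometric, so draw counts directly
    n_biased = int(labels.sum())
    counts = rng.hypergeometric(
        n_biased, labels.size - n_biased, set_size, size=config.replicates
    )
    if direction == "excess":
        extreme = int((counts >= observed).sum())
    elif direction == "deficit":
        extreme = int((counts <= observed).sum())
    else:
        raise ValueError("direction must be 'excess' or 'deficit'")
    return (1 + extreme) / (1 + config.replicates)


def read_snp_counts_tsv(path) -> list[SnpSiteCounts]:
    """Read the SNP count TSV: chrom, pos, strain, dna_ref, dna_alt, rna_ref, rna_alt, tissue."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strain", "dna_ref", "dna_alt", "rna_ref", "rna_alt", "tissue"],
        dtype={"chrom": str, "strain": str, "tissue": str},
    )
    return [
        SnpSiteCounts(
            r.chrom, int(r.pos), r.strain, int(r.dna_ref), int(r.dna_alt),
            int(r.rna_ref), int(r.rna_alt), r.tissue,
        )
        for r in df.itertuples(index=False)
    ]
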