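"""Synthetic data with known truth for every stage of the pipeline.

The generator emulates the study design the pipeline targets: three
reference replicates plus a panel of sample strains, per-site coverage at
~61x mean over exonic sequence, near-zero intergenic background, and
embedded events (whole-gene duplications, chimeras, recruited non-coding /
de novo regions, duplication-deletions) applied to carrier strains only.

Site counts are negative binomial around the exonic mean, with a small
gene-by-replicate lognormal random effect so replicate variance exceeds
raw Poisson noise and is autocorrelated along genes, which is what real
coverage tracks look like. Events act multiplicatively on the coverage
mean (the HMM consumes coverage, not reads, so read-level re-simulation
would add nothing the model can see).

Every draw flows from one ``numpy`` Generator seeded from the config, so a
fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage_io import (
    CoverageMatrix,
    Gene,
    GeneModelSet,
    write_depth_tsv,
    write_gene_models_gff3,
)
from .structures import ReadPairRecord

__all__ = [
    "SimEvent",
    "SimConfig",
    "SimTruth",
    "build_gene_models",
    "simulate_coverage",
    "simulate_read_pairs",
    "simulate_snp_counts",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class SimEvent:
    """One injected event.

    kind: whole_gene | chimera | de_novo | duplication_deletion | intergenic
    gene_index: anchor gene for gene-linked events (chimeras span this gene
    and the next one).
    fold: multiplicative expression change applied to carriers over the
    event's expressed interval (1.0 = dosage-buffered, no change).
    carriers: strain names carrying the duplication.
    de_novo_level: absolute coverage mean given to an activated intergenic
    region (de_novo events only).
    """

    kind: str
    gene_index: int = 0
    fold: float = 1.0
    carriers: tuple[str, ...] = ()
    de_novo_level: float = 20.0
    region_len: int = 500

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chr2L"
    n_genes: int = 36
    gene_length: int = 2000
    intergenic_gap: int = 1200
    utr_length: int = 150
    mean_exonic_coverage: float = 61.0
    intergenic_mean: float = 0.15
    nb_size: float = 400.0
    gene_effect_sd: float = 0.05
    gene_level_sd: float = 0.6
    pin_event_genes: bool = True
    n_strains: int = 6
    n_ref_reps: int = 3
    tissue: str = "testes"
    dup_flank: int = 150
    read_length: int = 76
    pair_jitter: int = 50
    events: tuple[SimEvent, ...] = ()

    @property
    def ref_names(self) -> list[str]:
        return [f"ref{i + 1}" for i in range(self.n_ref_reps)]

    @property
    def strain_names(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_strains)]

    @property
    def chrom_length(self) -> int:
        return self.n_genes * (self.gene_length + self.intergenic_gap) + self.intergenic_gap


@dataclass
class TruthRecord:
    kind: str
    dup_start: int
    dup_end: int
    expressed_start: int
    expressed_end: int
    fold: float
    genes: tuple[str, ...]
    carriers: tuple[str, ...]


@dataclass
class SimTruth:
    chrom: str
    records: list[TruthRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def duplication_spans(self) -> list[tuple[str, int, int]]:
        return [(self.chrom, r.dup_start, r.dup_end) for r in self.records]


def build_gene_models(config: SimConfig) -> GeneModelSet:
    """Deterministic plus-strand gene grid: two exons, one intron, UTRs.

    Gene i occupies [gap + i*(len+gap), ...+len). Exons are the first 40%
    and last 40% of the span; the 5'UTR is the leading ``utr_length`` bp of
    exon 1 and the 3'UTR the trailing ``utr_length`` bp of exon 2.
    """
    genes = []
    step = config.gene_length + config.intergenic_gap
    for i in range(config.n_genes):
        start = config.intergenic_gap + i * step
        end = start + config.gene_length
        e1 = (start, start + int(0.4 * config.gene_length))
        e2 = (end - int(0.4 * config.gene_length), end)
        genes.append(
            Gene(
                gene_id=f"G{i + 1:03d}",
                chrom=config.chrom,
                strand="+",
                start=start,
                end=end,
                exons=[e1, e2],
                utr5=[(start, start + config.utr_length)],
                utr3=[(end - config.utr_length, end)],
            )
        )
    return GeneModelSet(genes)


def _resolve_events(config: SimConfig, genes: GeneModelSet) -> list[TruthRecord]:
    records = []
    glist = genes.genes
    for ev in config.events:
        if ev.kind == "whole_gene":
            g = glist[ev.gene_index]
            ds, de = g.start - config.dup_flank, g.end + config.dup_flank
            records.append(
                TruthRecord("whole_gene", ds, de, g.start, g.end, ev.fold,
                            (g.gene_id,), ev.carriers)
            )
        elif ev.kind == "chimera":
            # junction fuses the 5' portion of the downstream gene to the 3'
            # portion of the anchor gene: dup runs from inside gene A to
            # inside gene B
            a = glist[ev.gene_index]
            b = glist[ev.gene_index + 1]
            ds = (a.start + a.end) // 2
            de = (b.start + b.end) // 2
            records.append(
                TruthRecord("chimera", ds, de, ds, de, ev.fold,
                            (b.gene_id, a.gene_id), ev.carriers)
            )
        elif ev.kind == "de_novo":
            # dup captures the 5' portion of the anchor gene plus the
            # upstream intergenic stretch it activates
            g = glist[ev.gene_index]
            region_end = g.start - 200
            region_start = region_end - 600
            ds = region_start - 100
            de = g.start + (g.end - g.start) // 3
            # for de_novo records ``fold`` stores the absolute activated level
            records.append(
                TruthRecord("de_novo", ds, de, region_start, region_end,
                            ev.de_novo_level, (g.gene_id,), ev.carriers)
            )
        elif ev.kind == "duplication_deletion":
            # only a sub-interval of the duplicated span is upregulated
            g = glist[ev.gene_index]
            ds, de = g.start - config.dup_flank, g.end + config.dup_flank
            mid = (g.start + g.end) // 2
            records.append(
                TruthRecord("duplication_deletion", ds, de, g.start, mid,
                            ev.fold, (g.gene_id,), ev.carriers)
            )
        elif ev.kind == "region":
            # a bare contiguous fold-change region inside an exon, for
            # HMM power checks; the dup span is the region itself
            g = glist[ev.gene_index]
            e1s, e1e = g.exons[0]
            rs, re = e1s, min(e1s + ev.region_len, e1e)
            records.append(
                TruthRecord("region", rs, re, rs, re, ev.fold,
                            (g.gene_id,), ev.carriers)
            )
        elif ev.kind == "intergenic":
            # a duplication in a gene desert: use the trailing gap
            ds = config.chrom_length - config.intergenic_gap + 100
            de = config.chrom_length - 100
            records.append(
                TruthRecord("intergenic", ds, de, ds, de, 1.0, (), ev.carriers)
            )
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        rec = records[-1]
        if rec.dup_start < 0 or rec.dup_end > config.chrom_length:
            raise ValueError(f"event {ev.kind} interval off chromosome")
    return records


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(float)


def simulate_coverage(config: SimConfig) -> tuple[CoverageMatrix, GeneModelSet, SimTruth]:
    """Simulate the per-site coverage matrix for all replicates and strains.

    Returns the coverage matrix (reference replicates first, then sample
    strains), the gene models, and the truth table. Exonic sites draw NB
    counts around the configured mean modulated by a per-gene-per-sample
    lognormal effect; intronic sites sit at 20% of the exonic mean and
    intergenic sites at the near-zero background. Carrier strains have
    event folds applied multiplicatively over the event's expressed
    interval (de novo events instead set an absolute activated level).
    """
    rng = np.random.default_rng(config.seed)
    genes = build_gene_models(config)
    truth = SimTruth(config.chrom, _resolve_events(config, genes))

    # per-gene expression levels, shared by all samples: real transcriptomes
    # span orders of magnitude, and that spread is what lets quantile
    # normalization preserve fold changes instead of clipping the top ranks
    levels = np.exp(rng.normal(0.0, config.gene_level_sd, size=config.n_genes))
    if config.gene_level_sd > 0:
        levels /= np.exp(config.gene_level_sd**2 / 2)  # mean-1 lognormal
    if config.pin_event_genes:
        # genes anchoring events sit exactly at the stated mean coverage
        for ev in config.events:
            if ev.kind != "intergenic":
                levels[ev.gene_index] = 1.0
                if ev.kind == "chimera":
                    levels[ev.gene_index + 1] = 1.0

    n_sites = config.chrom_length
    base = np.full(n_sites, config.intergenic_mean)
    gene_of_site = np.full(n_sites, -1)
    for gi, g in enumerate(genes):
        mean_g = config.mean_exonic_coverage * levels[gi]
        base[g.start:g.end] = 0.2 * mean_g  # intron floor
        for s, e in g.exons:
            base[s:e] = mean_g
        gene_of_site[g.start:g.end] = gi

    samples = config.ref_names + config.strain_names
    depth = np.empty((n_sites, len(samples)))
    for j, name in enumerate(samples):
        mean_j = base.copy()
        # gene-by-replicate random effect: shared along a gene, independent
        # across samples -> replicate variance above Poisson, autocorrelated
        effects = np.exp(rng.normal(0.0, config.gene_effect_sd, size=len(genes)))
        in_gene = gene_of_site >= 0
        mean_j[in_gene] *= effects[gene_of_site[in_gene]]
        if name not in config.ref_names:
            for rec in truth.records:
                if name in rec.carriers:
                    sl = slice(rec.expressed_start, rec.expressed_end)
                    if rec.kind == "de_novo":
                        mean_j[sl] = rec.fold
                    else:
                        mean_j[sl] = mean_j[sl] * rec.fold
        depth[:, j] = _nb_draw(rng, mean_j, config.nb_size)

    positions = np.arange(1, n_sites + 1, dtype=np.int64)
    cov = CoverageMatrix(config.chrom, positions, samples, depth)
    return cov, genes, truth


def simulate_read_pairs(
    config: SimConfig, truth: SimTruth, n_pairs: int = 4
) -> list[ReadPairRecord]:
    """Divergent read pairs marking each duplication junction in carriers.

    Each carrier strain of each truth record emits ``n_pairs`` divergent
    pairs with anchors jittered inward by up to ``config.pair_jitter`` bp
    from the true breakpoints, so the called span is contained in the truth
    span within jitter. Non-carriers emit nothing.
    """
    rng = np.random.default_rng(config.seed + 1)
    pairs = []
    for rec in truth.records:
        for strain in rec.carriers:
            for _ in range(max(n_pairs, 3)):
                j1 = int(rng.integers(0, config.pair_jitter + 1))
                j2 = int(rng.integers(0, config.pair_jitter + 1))
                ls = rec.dup_start + j1
                rs = rec.dup_end - j2 - config.read_length
                pairs.append(
                    ReadPairRecord(
                        strain=strain,
                        chrom=truth.chrom,
                        left_start=ls,
                        left_end=ls + config.read_length,
                        right_start=rs,
                        right_end=rs + config.read_length,
                        orientation="divergent",
                    )
                )
    return pairs


def simulate_snp_counts(
    config: SimConfig,
    truth: SimTruth,
    depth_per_library: int = 60,
    carrier_rna_ref_fraction: float = 0.5,
) -> pd.DataFrame:
    """Heterozygous-looking SNP counts inside whole-gene duplications.

    Carrier strains appear heterozygous (duplicate copies differ at one
    site): DNA reads split evenly; RNA reads split by
    ``carrier_rna_ref_fraction`` (0.5 = dosage-shared, asymmetric values
    emulate silencing of one copy). Non-carriers are balanced in both
    libraries.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    half = depth_per_library // 2
    for rec in truth.records:
        if rec.kind != "whole_gene":
            continue
        pos = (rec.expressed_start + rec.expressed_end) // 2 + 1
        for strain in config.strain_names:
            p = carrier_rna_ref_fraction if strain in rec.carriers else 0.5
            rna_ref = int(rng.binomial(depth_per_library, p))
            rows.append(
                {
                    "chrom": truth.chrom,
                    "pos": pos,
                    "strain": strain,
                    "dna_ref": half,
                    "dna_alt": depth_per_library - half,
                    "rna_ref": rna_ref,
                    "rna_alt": depth_per_library - rna_ref,
                    "tissue": config.tissue,
                }
            )
    return pd.DataFrame(rows)


def write_fixture_bundle(
    cov: CoverageMatrix,
    genes: GeneModelSet,
    truth: SimTruth,
    pairs: list[ReadPairRecord],
    snps: pd.DataFrame,
    outdir,
) -> dict[str, Path]:
    """Write the full plain-text bundle; re-reading reproduces the objects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "depth": out / "depth.tsv",
        "gff3": out / "genes.gff3",
        "dups": out / "duplications.bed",
        "pairs": out / "read_pairs.tsv",
        "snps": out / "snp_counts.tsv",
        "truth": out / "truth.tsv",
    }
    write_depth_tsv([cov], paths["depth"])
    write_gene_models_gff3(genes, paths["gff3"])
    with open(paths["dups"], "w") as fh:
        for rec in truth.records:
            fh.write(
                f"{truth.chrom}\t{rec.dup_start}\t{rec.dup_end}\t{rec.kind}"
                f"\t{len(rec.carriers)}\t.\n"
            )
    with open(paths["pairs"], "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.strain}\t{p.chrom}\t{p.left_start}\t{p.left_end}"
                f"\t{p.right_start}\t{p.right_end}\t{p.orientation}\n"
            )
    snps.to_csv(paths["snps"], sep="\t", header=False, index=False)
    pd.DataFrame(
        [
            {
                "kind": r.kind,
                "dup_start": r.dup_start,
                "dup_end": r.dup_end,
                "expressed_start": r.expressed_start,
                "expressed_end": r.expressed_end,
                "fold": r.fold,
                "genes": ",".join(r.genes),
                "carriers": ",".join(r.carriers),
            }
            for r in truth.records
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
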