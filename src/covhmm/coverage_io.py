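"""Coverage-track and gene-model I/O plus cross-sample normalization.

Per-site read depth (``samtools depth`` layout: chrom, 1-based position, one
depth column per sample) is the observable substrate for the expression HMM.
Depth tracks are quantile normalized per chromosome within a tissue so every
sample shares the same coverage distribution, and the reference replicates
are summarized into a per-site mean/variance track that parameterizes the
emission model.

Coordinates are 1-based inclusive in TSV/GFF inputs and outputs, 0-based
half-open internally and in BED output.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageMatrix",
    "ReferenceSummary",
    "Gene",
    "GeneModelSet",
    "read_depth_tsv",
    "write_depth_tsv",
    "quantile_normalize",
    "zscore_normalize",
    "summarize_reference",
    "read_gene_models",
    "write_gene_models_gff3",
]


class DepthFormatError(ValueError):
    """Malformed depth table (non-numeric depth, non-monotone positions...)."""


@dataclass
class CoverageMatrix:
    """Per-site depth for one chromosome across an ordered set of samples.

    ``positions`` are strictly increasing 1-based site coordinates;
    ``depth`` has one row per position, one column per sample, all
    entries >= 0 (raw reads or quantile-normalized reads).
    """

    chrom: str
    positions: np.ndarray
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim == 1:
            self.depth = self.depth.reshape(-1, max(len(self.samples), 1))
        if self.depth.shape != (len(self.positions), len(self.samples)):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.positions)} sites x {len(self.samples)} samples"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise DepthFormatError(
                f"positions not strictly increasing on {self.chrom}"
            )
        if self.depth.size and float(self.depth.min()) < 0:
            raise ValueError("negative depth")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def column(self, sample: str) -> np.ndarray:
        return self.depth[:, self.samples.index(sample)]

    def subset(self, samples: Sequence[str]) -> "CoverageMatrix":
        idx = [self.samples.index(s) for s in samples]
        return CoverageMatrix(
            self.chrom, self.positions.copy(), list(samples), self.depth[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.depth, columns=self.samples)
        df.insert(0, "pos", self.positions)
        df.insert(0, "chrom", self.chrom)
        return df


@dataclass
class ReferenceSummary:
    """Per-site mean and variance of the reference replicates."""

    mu: np.ndarray
    sigma2: np.ndarray
    n_reps: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 shapes differ")
        if self.sigma2.size and float(self.sigma2.min()) < 0:
            raise ValueError("negative variance")


def read_depth_tsv(
    path,
    sample_names: Sequence[str],
    fill_missing: tuple[int, int] | None = None,
) -> dict[str, CoverageMatrix]:
    """Read a samtools-depth-style TSV into one CoverageMatrix per chromosome.

    Columns are chrom, 1-based position, then one depth column per entry of
    ``sample_names``. ``samtools depth`` omits zero-coverage sites by
    default; pass ``fill_missing=(start, end)`` (1-based inclusive) to pad
    absent positions in that window with depth 0.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", *sample_names],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    try:
        pos = df["pos"].astype(np.int64)
        depth = df[list(sample_names)].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise DepthFormatError(f"non-numeric field in depth table: {exc}") from exc
    if np.isnan(depth).any():
        raise DepthFormatError("missing depth value in depth table")

    out: dict[str, CoverageMatrix] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        p = pos[sub.index].to_numpy()
        d = depth[sub.index.to_numpy()]
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            raise DepthFormatError(f"positions not strictly increasing on {chrom}")
        if fill_missing is not None:
            lo, hi = fill_missing
            full = np.arange(lo, hi + 1, dtype=np.int64)
            fd = np.zeros((len(full), len(sample_names)))
            fd[np.searchsorted(full, p)] = d
            p, d = full, fd
        out[str(chrom)] = CoverageMatrix(str(chrom), p, list(sample_names), d)
    return out


def write_depth_tsv(matrices: Iterable[CoverageMatrix], path) -> None:
    """Write CoverageMatrix objects back to the samtools-depth TSV layout."""
    frames = [m.to_frame() for m in matrices]
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)


def quantile_normalize(matrix: CoverageMatrix) -> CoverageMatrix:
    """Quantile normalize one chromosome's depth across samples.

    Each column's sorted values are replaced by the cross-sample mean of
    order statistics, so afterwards every sample has the same coverage
    distribution (hence the same mean and variance). Tied values within a
    column receive the mean of the targets for their rank range, which
    makes the transform deterministic and idempotent.

    The intended scope is one chromosome within one tissue, with the
    reference replicates included alongside the sample strains.
    """
    d = matrix.depth
    if d.shape[1] <= 1 or d.shape[0] == 0:
        return CoverageMatrix(
            matrix.chrom, matrix.positions.copy(), list(matrix.samples), d.copy()
        )
    target = np.mean(np.sort(d, axis=0), axis=1)
    out = np.empty_like(d)
    for j in range(d.shape[1]):
        col = d[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        mapped = target[ranks]
        # ties: average the targets over each tied run
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                mapped[order[s:e]] = target[s:e].mean()
        out[:, j] = mapped
    return CoverageMatrix(matrix.chrom, matrix.positions.copy(), list(matrix.samples), out)


def zscore_normalize(matrix: CoverageMatrix) -> CoverageMatrix:
    """Alternative normalization equalizing only mean and variance per column.

    Columns are affinely mapped to the cross-sample average mean/sd and
    clipped at zero. Weaker than full quantile normalization; provided for
    sensitivity analysis.
    """
    d = matrix.depth
    if d.shape[1] <= 1 or d.shape[0] == 0:
        return CoverageMatrix(
            matrix.chrom, matrix.positions.copy(), list(matrix.samples), d.copy()
        )
    means = d.mean(axis=0)
    sds = d.std(axis=0, ddof=0)
    t_mean, t_sd = means.mean(), sds.mean()
    out = np.empty_like(d)
    for j in range(d.shape[1]):
        sd = sds[j] if sds[j] > 0 else 1.0
        out[:, j] = (d[:, j] - means[j]) / sd * t_sd + t_mean
    return CoverageMatrix(
        matrix.chrom, matrix.positions.copy(), list(matrix.samples), np.clip(out, 0, None)
    )


def summarize_reference(
    ref: CoverageMatrix, variance_floor: float | None = None
) -> ReferenceSummary:
    """Per-site mean and unbiased (n-1) variance of the reference replicates.

    With a single replicate the variance is undefined; pass
    ``variance_floor`` to use that constant instead of raising.
    """
    n = len(ref.samples)
    if n < 2 and variance_floor is None:
        raise ValueError(
            "need >=2 reference replicates for a variance estimate "
            "(or configure variance_floor)"
        )
    mu = ref.depth.mean(axis=1)
    if n >= 2:
        sigma2 = ref.depth.var(axis=1, ddof=1)
        if variance_floor is not None:
            sigma2 = np.maximum(sigma2, variance_floor)
    else:
        sigma2 = np.full_like(mu, float(variance_floor))
    return ReferenceSummary(mu=mu, sigma2=sigma2, n_reps=n)


# ---------------------------------------------------------------------------
# gene models

@dataclass
class Gene:
    """One gene model: transcript span, merged exons, UTRs where annotated.

    Intervals are 0-based half-open. ``exons`` are merged (non-overlapping,
    sorted); UTR intervals, when present, are contained in the span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exonic_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def has_utrs(self) -> bool:
        return bool(self.utr5) and bool(self.utr3)


@dataclass
class GeneModelSet:
    genes: list[Gene]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gene_models(path) -> GeneModelSet:
    """Parse a GFF3 of gene/mRNA/exon (+ optional UTR) features.

    Exons overlapping within a gene (e.g. across isoforms) are merged into a
    single interval set. Exons extending outside the parent span are clamped
    with a warning. GFF3 coordinates (1-based inclusive) are converted to
    0-based half-open.
    """
    import gffutils

    text = open(path).read() if not isinstance(path, io.StringIO) else path.read()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return GeneModelSet([])
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        gid = gf.attributes.get("ID", [gf.id])[0]
        g = Gene(
            gene_id=gid,
            chrom=gf.seqid,
            strand=gf.strand or ".",
            start=gf.start - 1,
            end=gf.end,
        )
        exons, u5, u3 = [], [], []
        for child in db.children(gf.id):
            s, e = child.start - 1, child.end
            if s < g.start or e > g.end:
                warnings.warn(
                    f"feature {child.featuretype} [{s},{e}) outside gene "
                    f"{gid} span [{g.start},{g.end}); clamping"
                )
                s, e = max(s, g.start), min(e, g.end)
            if child.featuretype == "exon":
                exons.append((s, e))
            elif child.featuretype == "five_prime_UTR":
                u5.append((s, e))
            elif child.featuretype == "three_prime_UTR":
                u3.append((s, e))
        g.exons = _merge_intervals(exons)
        g.utr5 = _merge_intervals(u5)
        g.utr3 = _merge_intervals(u3)
        genes.append(g)
    return GeneModelSet(genes)


def write_gene_models_gff3(genes: GeneModelSet, path) -> None:
    """Write a GeneModelSet to GFF3 (gene/mRNA/exon/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tcovhmm\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\tID={mrna};Parent={g.gene_id}\n"
            )
            for kind, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for i, (s, e) in enumerate(ivs, 1):
                    fh.write(
                        f"{base}{kind}\t{s + 1}\t{e}{tail}\t"
                        f"ID={mrna}.{kind}{i};Parent={mrna}\n"
                    )
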