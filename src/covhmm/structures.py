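"""Tandem-duplication calling and structural-consequence classification.

Tandem duplications are called from divergently oriented read pairs — the
junction signature of a head-to-tail duplicated segment. Three or more
divergent pairs whose anchors lie within 25 kb of one another define one
call; its span is the outermost anchor extent. Calls at loci that also show
divergent pairs in the reference strain are dropped (mis-assembly or
technical artifact). Per-strain calls are then clustered across strains
when both breakpoints agree within 200 bp.

A tandem duplication of [x, y) creates the junction y|x. Classification
against gene models follows that junction geometry: a duplication boundary
interior to a gene donates the gene's 5' or 3' fragment (by strand), a
5' fragment fused across the junction to another gene's 3' fragment is a
chimera, a 5' fragment fused to intergenic sequence is recruited
non-coding sequence (the substrate of de novo gene origination), a full
transcript with both UTRs inside the span is a whole-gene duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .coverage_io import Gene, GeneModelSet

__all__ = [
    "ReadPairRecord",
    "DuplicationCall",
    "StructureClassification",
    "read_pair_tsv",
    "call_duplications",
    "cluster_across_strains",
    "classify_structures",
    "classifications_to_frame",
]

MAX_PAIR_SPAN = 25_000
MIN_SUPPORT = 3
CLUSTER_DIST = 200


@dataclass(frozen=True)
class ReadPairRecord:
    """One mapped read pair: anchor intervals (half-open) plus orientation."""

    strain: str
    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    orientation: str  # "divergent" or "proper"

    def __post_init__(self):
        if self.left_start > self.right_start:
            raise ValueError("left read must start before right read")

    @property
    def span(self) -> tuple[int, int]:
        return self.left_start, self.right_end


@dataclass
class DuplicationCall:
    """A tandem duplication span with its read-pair support and carriers."""

    chrom: str
    start: int
    end: int
    support: int
    strains: list[str] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.strains)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StructureClassification:
    dup: DuplicationCall
    kind: str  # whole_gene | chimera | gene_fragment | recruited_noncoding | intergenic
    genes: list[str] = field(default_factory=list)
    portions: list[str] = field(default_factory=list)  # "5prime"/"3prime"/"whole" per gene
    junction: tuple[int, int] | None = None  # (y, x): junction joins end to start


def read_pair_tsv(path) -> list[ReadPairRecord]:
    """Read the divergent/proper read-pair TSV (one row per pair)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "strain", "chrom", "left_start", "left_end",
            "right_start", "right_end", "orientation",
        ],
        dtype={"strain": str, "chrom": str, "orientation": str},
    )
    return [
        ReadPairRecord(
            r.strain, r.chrom, int(r.left_start), int(r.left_end),
            int(r.right_start), int(r.right_end), r.orientation,
        )
        for r in df.itertuples(index=False)
    ]


def _group_pairs(pairs: list[ReadPairRecord]) -> list[list[ReadPairRecord]]:
    """Single-linkage grouping of divergent pairs within the 25 kb span cap."""
    groups: list[list[ReadPairRecord]] = []
    for chrom in sorted({p.chrom for p in pairs}):
        chrom_pairs = sorted(
            (p for p in pairs if p.chrom == chrom),
            key=lambda p: (p.left_start, p.right_end),
        )
        current: list[ReadPairRecord] = []
        lo = hi = 0
        for p in chrom_pairs:
            if current:
                new_lo = min(lo, p.left_start)
                new_hi = max(hi, p.right_end)
                if new_hi - new_lo <= MAX_PAIR_SPAN:
                    current.append(p)
                    lo, hi = new_lo, new_hi
                    continue
                groups.append(current)
            current = [p]
            lo, hi = p.left_start, p.right_end
        if current:
            groups.append(current)
    return groups


def call_duplications(
    pairs: Iterable[ReadPairRecord],
    reference_pairs: Iterable[ReadPairRecord] = (),
    min_support: int = MIN_SUPPORT,
) -> list[DuplicationCall]:
    """Call tandem duplications for one strain from its divergent pairs.

    Groups of >= ``min_support`` divergent pairs whose anchors all lie
    within 25 kb form one call spanning the outermost anchor extent.
    Calls whose span overlaps any divergent pair of the reference strain
    are excluded. Output is deterministic and order-independent.
    """
    divergent = [p for p in pairs if p.orientation == "divergent"]
    ref_spans = [
        (p.chrom, *p.span)
        for p in reference_pairs
        if p.orientation == "divergent"
    ]
    calls = []
    for group in _group_pairs(divergent):
        if len(group) < min_support:
            continue
        chrom = group[0].chrom
        start = min(p.left_start for p in group)
        end = max(p.right_end for p in group)
        if any(rc == chrom and rs < end and start < re for rc, rs, re in ref_spans):
            # reference strain shows the same junction signature: artifact
            continue
        strains = sorted({p.strain for p in group})
        calls.append(
            DuplicationCall(chrom=chrom, start=start, end=end,
                            support=len(group), strains=strains)
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def cluster_across_strains(
    calls: Iterable[DuplicationCall], dist: int = CLUSTER_DIST
) -> list[DuplicationCall]:
    """Merge per-strain calls whose breakpoints both agree within ``dist`` bp.

    Start-to-start and end-to-end distances must each be <= ``dist``
    (single linkage). The merged span is the maximum extent across members
    and the frequency is the number of distinct carrier strains. Idempotent
    and independent of strain order.
    """
    todo = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    merged: list[DuplicationCall] = []
    for c in todo:
        hit = None
        for m in merged:
            if (
                m.chrom == c.chrom
                and abs(m.start - c.start) <= dist
                and abs(m.end - c.end) <= dist
            ):
                hit = m
                break
        if hit is None:
            merged.append(
                DuplicationCall(c.chrom, c.start, c.end, c.support, sorted(c.strains))
            )
        else:
            hit.start = min(hit.start, c.start)
            hit.end = max(hit.end, c.end)
            hit.support += c.support
            hit.strains = sorted(set(hit.strains) | set(c.strains))
    return merged


def _portion_at_boundary(g: Gene, boundary: int, side: str) -> str:
    """Which gene portion the duplication keeps when cut at ``boundary``.

    ``side`` is "left" when the boundary is the dup start x (the dup keeps
    the gene's sequence to the right of it) and "right" when it is the dup
    end y (the dup keeps the sequence to the left). Orientation then maps
    kept-right/kept-left to 3'/5' by strand.
    """
    keeps_right = side == "left"
    if g.strand == "-":
        keeps_right = not keeps_right
    return "3prime" if keeps_right else "5prime"


def classify_structures(
    dup: DuplicationCall, genes: GeneModelSet | Sequence[Gene]
) -> list[StructureClassification]:
    """Classify the structural consequences of one tandem duplication.

    A duplication may yield several classifications, one per affected gene
    (whole-gene records for each fully contained transcript, plus at most
    one junction-mediated record: chimera, recruited non-coding, or gene
    fragment). A duplication touching no gene is intergenic.
    """
    x, y = dup.start, dup.end
    chrom_genes = [g for g in genes if g.chrom == dup.chrom]
    out: list[StructureClassification] = []

    cut_at_x = [g for g in chrom_genes if g.start < x < g.end]
    cut_at_y = [g for g in chrom_genes if g.start < y < g.end]
    contained = [
        g for g in chrom_genes if x <= g.start and g.end <= y
        and g not in cut_at_x and g not in cut_at_y
    ]
    for g in contained:
        out.append(
            StructureClassification(
                dup=dup, kind="whole_gene", genes=[g.gene_id], portions=["whole"]
            )
        )

    # junction y|x: sequence ending just before y is fused to sequence from x
    fragments: list[tuple[Gene, str, str]] = []  # (gene, portion, side)
    for g in cut_at_x:
        if g in cut_at_y:
            continue  # dup internal to this gene; handled below
        fragments.append((g, _portion_at_boundary(g, x, "left"), "x"))
    for g in cut_at_y:
        if g in cut_at_x:
            continue
        fragments.append((g, _portion_at_boundary(g, y, "right"), "y"))

    internal = [g for g in cut_at_x if g in cut_at_y]
    for g in internal:
        out.append(
            StructureClassification(
                dup=dup, kind="gene_fragment", genes=[g.gene_id],
                portions=["internal"], junction=(y, x),
            )
        )

    five = [(g, side) for g, portion, side in fragments if portion == "5prime"]
    three = [(g, side) for g, portion, side in fragments if portion == "3prime"]

    if five and three:
        g5, _ = five[0]
        g3, _ = three[0]
        out.append(
            StructureClassification(
                dup=dup, kind="chimera",
                genes=[g5.gene_id, g3.gene_id],
                portions=["5prime", "3prime"],
                junction=(y, x),
            )
        )
    elif five:
        # 5' fragment meets intergenic sequence across the junction
        for g, side in five:
            out.append(
                StructureClassification(
                    dup=dup, kind="recruited_noncoding",
                    genes=[g.gene_id], portions=["5prime"], junction=(y, x),
                )
            )
    elif three:
        for g, side in three:
            out.append(
                StructureClassification(
                    dup=dup, kind="gene_fragment",
                    genes=[g.gene_id], portions=["3prime"], junction=(y, x),
                )
            )

    if not out:
        out.append(StructureClassification(dup=dup, kind="intergenic"))
    return out


def classifications_to_frame(
    classifications: Iterable[StructureClassification],
) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append(
            {
                "chrom": c.dup.chrom,
                "start": c.dup.start,
                "end": c.dup.end,
                "kind": c.kind,
                "genes": ",".join(c.genes),
                "portions": ",".join(c.portions),
                "junction": f"{c.junction[0]}|{c.junction[1]}" if c.junction else ".",
                "frequency": c.dup.frequency,
            }
        )
    return pd.DataFrame(rows)
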