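"""Decode site-level expression states for a strain carrying a chimera.

Simulates three reference replicates plus six sample strains at 61x mean
exonic coverage with one chimeric gene (3x upregulated duplicated segment)
in strain s01, then runs the full pipeline: quantile normalization,
reference summarization, emission scoring, forward-backward decoding and
block calling.
"""

import numpy as np

from covhmm import (
    UP,
    SimConfig,
    SimEvent,
    classify_gene_regions,
    decode_sample,
    simulate_coverage,
)

cfg = SimConfig(
    seed=11,
    n_strains=6,
    events=(SimEvent("chimera", 10, fold=3.0, carriers=("s01",)),),
)
cov, genes, truth = simulate_coverage(cfg)
result = decode_sample(cov, cfg.ref_names, "s01")

rec = truth.records[0]
exonic = np.zeros(cov.n_sites, dtype=bool)
for gid in rec.genes:
    for s, e in genes.get(gid).exons:
        exonic[max(s, rec.dup_start):min(e, rec.dup_end)] = True
up_frac = np.mean(result.track.state[exonic] == UP)

print(f"chromosome sites decoded:      {cov.n_sites}")
print(f"genome-wide up-site fraction:  {result.background_rate:.4f}")
print(f"up fraction, duplicated exons: {up_frac:.3f}")
print(f"expression blocks (>=50 bp):   {len(result.blocks)}")

# gene-level call on the duplicated segments of the two parental genes
regions = {g: (rec.dup_start, rec.dup_end) for g in rec.genes}
calls = classify_gene_regions(
    result.blocks, [genes.get(g) for g in rec.genes], regions
)
for c in calls:
    print(
        f"  {c.gene_id}: {c.covered_bp}/{c.exonic_bp} exonic bp in up blocks "
        f"({c.fraction:.1%}) -> {'UPREGULATED' if c.upregulated else 'stable'}"
    )

print(
    "\nThe duplicated chimera segment decodes as upregulated at nearly every"
    "\nsite while the genome-wide background stays near a few percent — the"
    "\nsignature separating regulatory changes from coverage noise."
)
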