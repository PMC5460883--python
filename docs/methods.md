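# Methods

## The site-level expression model

The pipeline treats per-site RNA-seq coverage, not per-gene counts, as the
unit of inference. This is what makes it usable for mutations that create
gene structures absent from any annotation: chimeric fusions, duplicated
fragments, and newly transcribed intergenic sequence.

**Normalization.** Coverage tracks (one depth column per sample, from
`samtools depth`) are quantile normalized per chromosome within a tissue:
each column's sorted values are replaced by the cross-sample mean of order
statistics, so every sample has the same coverage distribution. Tied
values within a column receive the mean of the rank-range targets, which
is deterministic. Note that with ties this dialect is not exactly
idempotent (a tied pair keeps its tie while the target may not), though it
is idempotent on tie-free data; a mean/variance-only (z-score) mode is
provided for sensitivity analysis. `samtools depth` omits zero-coverage
sites by default; absent positions inside a requested window are treated
as depth 0, matching the producing tool's convention. Coordinates are
1-based inclusive in TSV/GFF, 0-based half-open internally and in BED.

**Reference summary.** The (three, in the motivating design) reference
replicates give per-site mean μ and unbiased (n−1) sample variance σ².
With n = 3 the per-site variance estimate is noisy; the HMM's transition
smoothing is what makes per-site calls stable despite this.

**Emissions.** With sample coverage x, the log fold change L = ln(x/μ) is
modelled as Gaussian with delta-method variance s² = 2σ²/μ² under no
change. The three states place the true mean at 0 and at the two-sided
critical values ±c, c = z₍₁₋α/₂₎·s (α = 0.05 by default, configurable).
Emission scores are tail probabilities, oriented so they rank states
monotonically in L:

* stable = 2(1 − Φ(|L|/s)) — the two-sided p-value under no change;
* up = Φ((L − c)/s) — nondecreasing in L, equal to ½ at L = c;
* down = 1 − Φ((L + c)/s) — nonincreasing in L.

These are scores, not normalized densities; the HMM uses them
unnormalized, so only within-site relative magnitudes matter. A literal
"symmetric tail" orientation (up = 1 − Φ((L−c)/s)) is retained behind
`EmissionParams(orientation="literal")` for comparison; it is non-monotone
in L and misranks states, which is why the monotone orientation is the
default.

Edge rules: μ < 0.5 normalized reads marks a silent reference site, where
the fold-change model is meaningless — sample coverage ≥ 5 reads scores
0.95 for up, otherwise 0.95 for stable, the residual 0.05 split equally.
Zero sample coverage with expressed reference uses L = ln(ε/μ) with
ε = 0.5 (half a normalized read), finite and strongly favoring down.
Zero reference variance is floored at σ² = 10⁻⁶ so constant replicate
tracks do not produce infinite test statistics.

**Chain and decoding.** π₀ = (0.05, 0.9, 0.05); transition matrix 0.8
diagonal, 0.1 off-diagonal. Decoding uses forward–backward posteriors
with per-site scaling (no underflow at any chain length); the per-site
argmax maximizes the expected number of correct site calls, the right
loss for site-specific testing — Viterbi's most-likely-path criterion is
deliberately not used. Exact posterior ties decode to stable
(conservative). Baum–Welch (EM on π₀ and the transition matrix, emissions
fixed) is available to check sensitivity to the sticky transition prior;
its log-likelihood trace is nondecreasing by construction and a
single-site chain returns the start parameters untouched.

## Calling rules

* **Blocks**: maximal runs of identical non-stable state covering ≥ 50
  contiguous bp. Contiguity is strict in genomic coordinates: a stable
  site, a state switch, or a hole in the site track ends the run.
* **Gene-level calls**: a gene — or, for chimeras, the duplicated 5′ or 3′
  segment — is upregulated when ≥ 50% of its annotated exonic bp lies in
  qualifying up blocks; genes upregulated in at least one strain count as
  upregulated in aggregate. The fraction is invariant to how exons are
  split into abutting intervals.
* **De novo transcription**: up blocks with zero exon overlap, per-site
  reference mean ≤ 2.0 at every block site (the per-site reading is
  stricter than a block-mean rule and is the one implemented), and total
  intersection with a tandem duplication span ≥ 200 bp.
* **Background and enrichment**: the background rate is the genome-wide
  fraction of up-state sites (computable pooled or per tissue); exact
  binomial tests use the minimum-likelihood two-sided convention, which
  reproduces the printed reference p-values from the printed counts.

## Duplication calling and classification

Divergent (outward-facing) read pairs mark tandem-junctions. Per strain,
single-linkage groups of pairs whose outermost anchor span stays within
25 kb and with ≥ 3 members become calls; the span is the outermost anchor
extent. How overlapping groups with large internal spread should be split
is underdetermined — single linkage with the 25 kb cap is the choice here.
Calls overlapping any reference-strain divergent pair are vetoed
(mis-assembly / technical artifact). Across strains, calls merge when both
breakpoints agree within 200 bp (start-to-start *and* end-to-end — the
reading that keeps distinct nearby events separate); frequency is the
carrier-strain count.

Classification of a duplication [x, y) follows the tandem junction y|x.
A boundary interior to a gene donates a fragment — on the plus strand, x
donates the 3′ portion and y the 5′ portion; minus strand mirrored. A 5′
donor fused to a 3′ donor is a chimera; a 5′ donor fused to intergenic
sequence is recruited non-coding sequence; a lone 3′ donor or an
internal-to-one-gene duplication is a gene fragment; a transcript fully
inside the span with both UTRs is a whole-gene duplication (one record per
captured gene — counts are per gene, not per duplication); no gene contact
means intergenic. When gene models lack UTRs, whole-gene status falls back
to the transcript span with a logged caveat.

## Auxiliary statistics

Mean fold change of a segment = mean sample coverage / mean reference
coverage, the denominator floored at one read (the floor applies to the
segment summary; a per-site floor mode exists for sensitivity). Dosage
sharing: at sites that look heterozygous in genomic DNA, a two-sided
Fisher exact test compares DNA ref/alt vs RNA ref/alt counts, applied
only when both libraries have ≥ 10 reads; sites significant (α = 0.05,
uncorrected screen by design) in any strain *lacking* the duplication are
filtered out as ordinary allele-specific expression. Rank-sum comparisons
report the Mann–Whitney U of the first sample (R's `wilcox.test` W
convention), exact for small tie-free samples. The proportion test is
Pearson's chi-squared with 1 df and no continuity correction. The
tissue-bias test resamples gene sets without replacement (10,000
replicates by default) and reports the add-one-corrected one-sided
empirical p, (1 + #extreme)/(1 + replicates); since bias labels are
boolean and exchangeable, the resampled counts are drawn directly from
the exact hypergeometric null.

## The synthetic-data generator

The generator emulates the motivating study design: 3 reference
replicates plus a strain panel, ~61× mean exonic coverage, near-zero
intergenic background (0.15 normalized reads), and events carried by a
subset of strains. Genes sit on a deterministic plus-strand grid (36
genes × 2 kb with 1.2 kb gaps by default, two exons flanking one intron,
UTRs at the span ends). Per-gene expression levels are lognormal (sd 0.6
on the log scale, normalized to mean 1, drawn once and shared by all
samples) — the orders-of-magnitude spread of real transcriptomes, and the
property that lets quantile normalization preserve fold changes instead
of clipping them at the top of the rank distribution. Genes anchoring
events are pinned to the stated 61× mean so injected effects happen at
the nominal study coverage.

Site counts are negative binomial (size 400 → variance ≈ mean at 61×, the
stated replicate-noise regime) multiplied by a per-gene-per-sample
lognormal random effect (sd 0.05) that makes replicate variance exceed
raw count noise and autocorrelate along genes, as real coverage does.
Events multiply the coverage mean over their expressed interval in
carrier strains (de novo events instead set an absolute activated level,
20 by default); the HMM consumes coverage, so read-level re-simulation
would add nothing the model can see. Duplication junctions emit ≥ 3
divergent read pairs with anchors jittered inward up to 50 bp. SNP count
tables make carriers look heterozygous with a configurable RNA allele
fraction (0.5 = dosage shared). Everything derives from one seeded
generator: fixed seed, byte-identical output bundle.

What the generator does *not* emulate — mappability artifacts, GC and
positional coverage bias, intron signal from unspliced pre-mRNA,
isoform structure, library-size differences between strains — bounds what
passing tests show: they demonstrate the inference machinery is correct
and well-calibrated under the stated noise model, not that real-data
artifact filtering is solved.

## Problem sizes and numerical choices

Simulated chromosomes are ~116 kb (36 genes) with 4–9 samples — large
enough for stable background-rate estimates (~10⁵ sites) while keeping
a full pipeline run around a second. Baum–Welch recovery uses 10⁵ sites.
Forward–backward is validated against exhaustive 3^L path enumeration for
chains up to length 8 (deviation < 10⁻¹⁰ demanded; observed ~10⁻¹⁵).
Posterior rows are normalized to 1 within 10⁻⁹. EM stops at ΔlogL < 10⁻⁴
(acceptance script) or 10⁻⁶ (library default) or 60–100 iterations.

## Known limitations

* The 3-replicate variance estimate is per site and noisy; calls lean on
  the transition prior for stability, so isolated single-site changes are
  (by design) hard to call.
* Quantile normalization assumes samples share a distribution shape; a
  strain with massive global expression change violates this.
* Breakpoints are resolved only to divergent-pair anchor extents
  (±read-length scale), not base pairs.
* Classification assumes one junction per duplication; nested or
  overlapping duplications and secondary deletions are represented in the
  simulator (duplication-deletion events) but classified only by their
  expression footprint, not their full structure.
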