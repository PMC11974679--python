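# Methods

This note documents the statistical procedures, conventions and design
choices behind `amdprio`, and what its synthetic data do and do not emulate.

## Coordinates and data model

All genomic coordinates are 0-based half-open `[start, end)` internally; a
point `p` lies in an interval iff `start <= p < end`. Variant tables from
1-based sources are converted once, at the reader boundary
(`read_variant_table(one_based=True)`). Chromosome names are compared as
exact strings — no `chr`-prefix normalization — because the synthetic data
control their own naming; users of real data must harmonize naming upstream.
Contact maps are stored dense per chromosome; this is a deliberate
desk-scale choice (the toy genome is 2 × 10 Mb) and would not scale to a
full mammalian genome.

## Catalog construction

LD expansion retains variants with squared dosage correlation R² strictly
above the threshold (default 0.5) to at least one index variant, each
annotated with its maximal R² and that index's locus. Index variants are
included by an explicit rule (R² = 1 to self), not by the threshold, which
avoids the ambiguity of a strict inequality at 1.0. Index substitution (for
indexes missing from the genotype panel) is caller-supplied via an explicit
table: the posterior probabilities that would rank substitutes come from an
external GWAS and are not recomputable here.

Credible-set merging is a union keyed on (chrom, pos, ref, alt); when both
sources carry a key, the expanded record wins because it holds the R²
annotation. The same rsid appearing with different alleles raises.

Consequence classification uses a fixed vocabulary; unknown labels raise
rather than defaulting to noncoding. Splice-altering labels route to
`protein_altering`: they change the protein product even though the base
substitution is noncoding in the literal sense. This is a judgment call —
the alternative (routing splice-region variants to noncoding) is defensible,
and the mapping table is importable and overridable.

AlphaMissense bins use strict inequalities: likely benign < 0.34, likely
pathogenic > 0.565, ambiguous otherwise (scores exactly at a boundary are
ambiguous).

Printed percentages are rounded half-away-from-zero to one decimal; this is
the rounding that reproduces conventionally printed summary figures, and it
is pinned in `round_half_away` so summaries are bit-stable.

## Chromatin atlas

Cell QC keeps a nucleus iff all five gates hold: 200–10,000 RNA transcripts
(inclusive), mitochondrial fraction < 1 %, ribosomal fraction < 5 %, TSS
enrichment > 4, and > 1,000 ATAC fragments (strict bounds as stated).

Promoter windows span 2,000 bp upstream to 100 bp downstream of the TSS,
strand-aware and clipped at chromosome boundaries; under the half-open
convention a + strand TSS `t` gives `[t − 2000, t + 101)`.

Variant accessibility uses the variant's single reference position (point
intersection), not the ref-allele span. The catalog is SNP-dominated; for
indels the point convention under-counts by at most the allele length, and
callers can expand indels to intervals themselves if that matters.

The generic group comparison (marker peaks/genes, differential
accessibility) is a Wilcoxon rank-sum test (mid-ranks, normal approximation,
continuity correction — scipy's asymptotic Mann-Whitney) with
Benjamini-Hochberg FDR across features, gated on the log2 fold change of
group means with a pseudocount of 1 (configurable). The pseudocount keeps
zero-mean groups defined; whether the original marker calling used
pseudocounted means is not knowable from the calling conventions alone, so
the choice is documented rather than claimed to match. "Expressing fraction"
is the fraction of group samples with a nonzero value. Threshold presets:
marker peaks log2FC ≥ 0.5 / FDR ≤ 0.1; differential accessibility ≥ 0.5 /
≤ 0.25; marker genes ≥ 1 / fraction ≥ 0.6; subpopulation genes ≥ 0.5 /
fraction ≥ 0.3.

## Enhancer connectome

Correlation-based links (co-accessibility, peak-gene) use Pearson
correlation on untransformed pseudo-bulk signal, and the cutoff (default
0.3) applies to the *signed* value — anticorrelated pairs never pass. An
absolute-value mode exists (`use_absolute=True`) because the signed/absolute
choice is a genuine ambiguity in co-accessibility conventions. The
co-accessibility window defaults to 250 kb (the same maximum distance as
peak-gene links). A peak is co-accessible with a gene's promoter iff it is
linked to at least one peak overlapping the promoter window.

Loop linking requires the variant (point) in one anchor and the gene's
promoter window or TSS overlapping the *partner* anchor; a variant and TSS
in the same anchor only is not a link. Anchor/peak overlap means ≥ 1 shared
base.

ABC scoring: activity is the geometric mean of ATAC and H3K27ac signal over
the element (the ABC model's published activity definition); contact is the
map value between the element-midpoint bin and the TSS bin, with the
diagonal entry for same-bin pairs and the map's own distance-decay profile
(mean contact at that bin distance) for bins outside the map. Per gene,
unthresholded scores over the candidate set sum to exactly 1; connections
are reported at score > 0.025 with element-TSS distance ≥ 500 bp. The
candidate window defaults to 5 Mb in the library and 1 Mb in the pipeline
config (the toy genome's loci are far smaller). Genes whose candidates all
have zero activity × contact are skipped with one aggregated warning.

Strategy-overlap summaries divide the pairwise intersection by the *smaller*
set; this denominator is a documented, configurable choice because overlap
ranges are often reported without one.

## STARR-seq analysis

Read layout is insert + constant adapter (`GCTAGCCATTGCGTGTAGAG`) + 10-nt
barcode. Parsing is exact-match: the adapter must occur, the trailing
barcode must be exactly 10 nt, and the insert must match an oligo reference
sequence exactly (no barcode error correction — none is defined for this
design). Unique barcodes per oligo per sample are set cardinalities, so PCR
duplicates count once and parsing is order-invariant.

QC discards oligos with < 5 unique barcodes in *any* replicate (input or
output); a SNP survives only if both allele oligos survive, since allelic
analysis is paired.

Normalization is median-of-ratios against the per-oligo geometric mean
(size factor = median over all-positive oligos of count/geometric mean) —
the standard count-model normalization, re-implemented here so its
convention is pinned and testable.

Both the enhancer and allelic tests are moderated one-sample t-tests of
replicate-wise log ratios against zero, with limma-style empirical-Bayes
shrinkage of per-SNP variances: residual variances are modeled as scaled-F,
the prior df solved from the trigamma moment identity by Newton iteration,
and posterior variances are `(d·s² + d0·s0²)/(d + d0)` with t df `d + d0`.
A pseudocount of 0.5 stabilizes logs of normalized counts. For the enhancer
test, ref+alt counts are combined per SNP and each output replicate is
paired with the same-index input replicate (when replicate counts match), so
input sampling noise enters the replicate-wise variance; with unequal
replicate counts the mean normalized input is the reference. For the allelic
test, log2(alt/ref) is formed within each output replicate (paired mode).
Enhancer calls use |log2FC| > log2(1.5) = 0.585 and adjusted p < 0.05 in
both directions by default, with depleted (negative) oligos flagged; an
enrichment-only mode restricts to positive effects.

The control-percentile threshold uses linear interpolation between order
statistics at `h = q·(n − 1)` (numpy's default) — pinned because percentile
conventions differ and the functional-SNP call is strict ("exceeding").
Functional SNPs are the conjunction: inside an enhancer, adjusted p < 0.05,
|log2FC| strictly above the control 80th percentile. QQ comparisons evaluate
both groups' |log2FC| quantiles at probabilities (k − 0.5)/n.

## Predicted variant effects

Effect size is the mean over model folds of log2(alt/ref) per (variant,
cell type); counts must be positive and ≥ 2 folds are required. The
per-cell-type p-value is a one-sided Poisson tail of the fold-averaged
alternative count with rate equal to the fold-averaged reference count.
Predicted counts are continuous, so the count is rounded to the nearest
integer before the tail sum; the tail direction adapts to the observed
change (upper tail for gains, lower for losses), which yields small p-values
for effects of either sign — consistent with calling on |log2FC|. Whether
the original scheme always used the upper tail is not determinable; the
direction-adaptive choice is documented, not claimed to match. Fisher
combination uses χ² with 2k df; exact zeros are clipped at 1e-300 with a
warning. BH adjustment is the step-up rule over all scored variants. High
effect = max |log2FC| over cell types > 0.25 AND FDR < 0.01, both strict.

## Integration

The criteria matrix is restricted to variants accessible in ≥ 1 RPE/choroid
cell type. Peak-level criteria (promoter co-accessibility, peak-gene
correlation, ABC) are inherited from the variant's containing peak(s); a
variant inside two peaks inherits the union. Loop linking is evaluated at
the variant position directly; the remaining four criteria are rsid-set
memberships. Prioritized = n criteria ≥ 3 (inclusive). Locus reports rank
candidates by criteria met, breaking ties by |allelic log2FC| (descending)
then rsid, so reports are deterministic; a locus whose index variants are
all inaccessible while a non-index variant is prioritized is flagged as an
"index inaccessible, alternative candidate" pattern.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments including the seed, and all
outputs pass the package's own readers after a write/read round trip.

- **Genotypes** — LD blocks built by copying a latent haplotype pair and
  flipping partner alleles with probability `(1 − √r²)/2`, which gives the
  target dosage R² in expectation in closed form (MAF 0.5 by default).
  Blocks are independent. No recombination maps, no realistic MAF spectrum.
- **Atlas** — gene expression and peak accessibility are lognormal
  transforms of latent Gaussian factors; planted peak-gene pairs share a
  factor at the stated correlation. The lognormal transform (σ = 0.3)
  attenuates the observed Pearson r a few percent below the latent value —
  immaterial at planted 0.9 vs cutoff 0.3, and stated so recovery tests are
  honest. Promoter-peak factors are independent of expression factors, an
  intentionally unrealistic disentanglement that lets the promoter-
  co-accessibility and peak-gene criteria be planted independently.
- **Contacts** — background contact between bins at distance d is
  `base·max(d,1)^(−γ)` (γ = 1 by default, base 50); planted loops multiply
  their anchor-bin pair. Against this decay a focal loop is the row maximum
  of observed/expected, not of raw contact (near-diagonal bins always
  dominate raw contact).
- **STARR-seq** — unique-barcode counts are negative binomial with variance
  μ + αμ². Default α = 0.005: deduplicated barcode counts are
  near-Poisson (each barcode is approximately an independent molecule), with
  mild extra dispersion from transfection and library bottlenecks — at an
  output mean of 300 this gives variance ≈ 2.5× Poisson. Default means are
  3,000 input and 300 output barcodes per oligo with four replicates,
  matching the scale of deeply sequenced reporter libraries. Planted
  enhancers multiply output means by 2^activity; allelic effects split
  ±effect/2 between alleles. Both alleles share an oligo baseline
  (lognormal, σ = 0.3), so allelic ratios are baseline-free.
- **Predicted counts** — per-fold ref/alt counts with multiplicative
  lognormal fold jitter (σ = 0.02) around a uniform base count (200–800);
  planted variants scale alt by 2^effect in one cell type.
- **eQTLs** — exactly round(fraction × n) variants get FDR ≤ 0.05 in one
  randomly chosen tissue region.

The integrated study (`simulate_study`) plants, per accessible variant, an
explicit profile of the eight criteria (functional-SNP always implies
enhancer) and realizes each with strong effects: latent correlation 0.9 at
200 pseudo-bulk samples, STARR activity/allelic log2FC 2.0 at four
replicates, predicted effect 1.0, loop enrichment 5×. Only planted enhancer
elements carry H3K27ac signal, so per-gene ABC normalization concentrates
score mass on them; background peaks are kept ≥ 2 kb from every catalog
variant and promoter window so accessibility and criteria are exactly as
planted. At these settings per-variant recovery probability is ≈ 1 at any
seed, which is what makes the planted-vs-recovered equality of the
end-to-end test meaningful. Passing on these data shows the chain of
thresholds, tests and bookkeeping is implemented correctly; it does not show
the statistics are powered for weak real-data effects, nor that the
generator's independence assumptions (no confounding between criteria, no
batch structure, no LD between loci) hold in real tissue.

Default problem sizes (8 loci, ~1,050 peaks, 200 pseudo-bulk samples, ~450
reporter SNPs, 5 folds × 3 cell types) were chosen so a full synthetic run
completes in seconds while every stage still crosses chromosome boundaries
and exercises its thresholds.

## Numerical choices and degenerate inputs

- Constant accessibility/expression profiles are skipped (correlation
  undefined) with a warning; constant dosage vectors raise in R².
- All per-SNP replicate log-ratios identical ⇒ residual variance 0 ⇒ the
  moderated test degenerates gracefully (t = 0, p = 1 for zero means).
- BH adjustment uses a stable mergesort so ties adjust deterministically.
- Empty enhancer target sets, empty control sets and empty catalogs raise or
  warn per function contract rather than returning silent zeros.
- Size factors require at least one oligo with positive counts in every
  sample; otherwise the median-of-ratios reference is undefined and the
  function raises.

## Known limitations

- No real-genome handling: no `chr` normalization, no tabix/bigWig/HDF5, no
  blacklist filtering; real peak calls, loop calls and model predictions are
  assumed to arrive pre-computed in the supported text formats.
- The moderated-t enhancer test stands in for a negative-binomial GLM; at
  high counts the two agree closely, but very low-count oligos (near the QC
  floor) are better served by a count model.
- Strategy-overlap and marker-enrichment normalizations depend on documented
  denominator choices; compare like with like when benchmarking.
- The prioritization rule is evidence counting, not causal inference:
  criteria are correlated in real data, and the ≥ 3-of-8 rule inherits any
  redundancy among them.
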