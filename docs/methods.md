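# Methods

## The measurement model

NET-seq-style libraries sequence the 3′ end of the nascent RNA, so the 5′
end of each aligned read is the genomic position of the transcriptionally
engaged polymerase at single-base resolution, with strand specificity. All
density computations in this package therefore reduce an alignment to one
stranded base: `start` for a plus-strand read, `end − 1` for a minus-strand
read. ATAC-seq reads are reduced the same way (each mate's 5′ end is a
transposase insertion point) but with strand collapsed, and no Tn5 +4/−5
shift is applied — the two assays are deliberately processed identically so
that promoter accessibility and promoter Pol II density are measured over
bp-for-bp identical windows. A configuration flag exists to enable the Tn5
shift for users who want conventional ATAC coordinates.

Library size is the number of mapped, primary alignments (secondary and
supplementary records excluded); records with MAPQ ≤ 10 are discarded
before density building. Three normalizations are used downstream:

| scale | definition | used for |
|---|---|---|
| RPM | value × 10⁶ / library size | pausing index input |
| RPKM | count × 10⁹ / (length × library size) | gene coverage filter (> 1) |
| RPGC | value × genome size / total signal | metagene profiles (genome mean 1×) |

The pausing index is a ratio of mean densities, so it is invariant under
any positive rescaling of a track; RPM is kept for comparability of the
intermediate promoter/body means across samples.

## Coordinates and windows

Internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted on parse, BED-family formats pass through natively. The gene
anchor is the canonical transcript's open reading frame: TSS and TES are
its 5′ and 3′ ends in transcription direction (for a minus-strand gene the
stored TSS is the exclusive right end of the span, so all window arithmetic
mirrors cleanly under the half-open convention).

* Promoter window: "TSS ± 200 bp" is implemented as the inclusive 401-bp
  interval [TSS − 200, TSS + 201), symmetric in genomic coordinates
  regardless of strand. The inclusive reading is the natural one for "±";
  because of the one extra base it is center-symmetric but not exactly
  interval-mirror-involutive, which the tests document.
* Gene body: [TSS + 200, TES − 200) in transcription direction; requires a
  span above 400 bp, guaranteed for selected genes (> 2 kb).
* Narrow pause window: [TSS + 20, TSS + 100), the 80-bp zone where
  promoter-proximally paused polymerase accumulates; on the minus strand
  the half-open mirror [TSS − 100, TSS − 20).

Gene selection retains protein-coding genes with span > 2,000 bp (strict)
whose span, extended by 2,500 bp on both sides, overlaps no other annotated
gene's span. The isolation test uses the neighbours' plain spans, not their
extended envelopes, to avoid double-counting the buffer. Canonical
transcript ties (equal CDS or cDNA length) break to the lexicographically
smallest transcript id for determinism.

## Pausing analysis

Per gene and sample, PI = (mean sense density over the promoter window) /
(mean sense density over the gene body). Genes with zero sense body signal
in any sample are excluded — the alternative, an infinite PI, is
incompatible with the downstream cap filter, which retains only genes with
PI ≤ 10 in *all* samples. Pausing categories follow high: PI ≥ 3,
moderate: 1.5 ≤ PI < 3, low: PI < 1.5; a configuration switch moves the
boundary value 1.5 into the low class instead. Per-condition PI is the
arithmetic mean of replicate PIs, and fold changes are
log2(PI_b / PI_a) on those means. The promoter-accessibility integration
joins per-gene PI fold changes with accessibility fold changes computed
over the identical promoter windows and reports the fraction of genes in
each sign quadrant; an exactly zero fold change counts as "up", a boundary
that no simulated gene hits.

## Enhancer identification

Replicate peak sets are flattened into the merged union of all peaks;
a merged region is a consensus region when at least `min_support` distinct
samples overlap it by ≥ 1 bp (union-merge was chosen over intersection;
both are available). Active enhancers are H3K27ac consensus regions with
zero overlap with H3K4me3 consensus regions (H3K4me3 marks promoters),
zero overlap with any TSS ± 1 kb window, and ≥ 1 bp overlap with an ATAC
consensus region. All three predicates are recorded per candidate in a
rule trail. Overlap semantics are ≥ 1 bp throughout, matching standard
interval-tool defaults. Genomic feature annotation uses midpoint
containment with precedence promoter > 5′ UTR > exon > intron > distal
intergenic (configurable); the 5′ UTR is approximated as exonic sequence
upstream of the ORF start.

## Differential statistics

Size factors follow the median-of-ratios definition — per sample, the
median over all-positive rows of count / row geometric mean — rescaled to
geometric mean one.

The two-group Wald test models normalized counts per region as NB2 with a
shared dispersion α. The raw per-region α is the pooled within-group
method-of-moments excess (s² − μ)/μ², which at 3 replicates per group is
far too noisy to calibrate a test: used directly it yields ~12% type-I
error at nominal 5% on overdispersed nulls. We therefore share information
across regions, shrinking the raw estimate toward the across-region mean
excess with 20 prior degrees of freedom, then flooring at 10⁻⁸ (the floor
is the Poisson fallback). With this moderation the measured type-I error
on seeded null simulations (2,000 regions, 3 vs 3) is 0.042 (Poisson null)
and 0.054 (NB null, α = 0.05), and the multi-condition LRT gives 0.056.
The Wald statistic is log2FC / SE with a delta-method SE,
Var(log mean) ≈ 1/(n·μ) + α/n per group, referred to a standard normal;
groups with zero mean use a half-count pseudo-mean to keep the SE finite,
and all-zero regions are reported flagged with p = 1 and log2FC = 0. The
LRT fits one NB mean per condition against a single shared mean with the
same moderated dispersion and refers 2·Δlogℓ to χ² with (levels − 1)
degrees of freedom. There is no dispersion trend fitting, outlier
(Cook's) filtering or independent filtering: the tests are transparent,
calibrated stand-ins, expected to agree with full-featured count packages
in direction and FDR behaviour but not numerically.

For trajectory analysis, log2(normalized count + 1) per-condition means
replace a variance-stabilizing transform (a documented simplification).
Genes are compared by Kendall distance d = 1 − τ_b (tie-corrected,
d ∈ [0, 2]); constant profiles have undefined τ and are excluded.
Clustering is classical divisive analysis (DIANA): repeatedly split the
cluster with the largest diameter by the splinter procedure — seed the
splinter with the object of maximal average dissimilarity, then migrate
objects while their average dissimilarity to the remainder exceeds that to
the splinter — cutting at k clusters (default 4, a configuration
parameter). All ties break to the lowest index, making the procedure
deterministic. The Wilcoxon rank-sum test uses the tie-corrected normal
approximation with continuity correction; the two-proportion z-test uses
the pooled-variance closed form.

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes, not
sequence-level reality: no read sequences, no alignment errors, no
duplicates, no chromatin context beyond the programmed enrichments.
Passing tests therefore demonstrate correctness of the computations and
recoverability of programmed effects at realistic depths — not robustness
to mapping artifacts or biological confounders.

Genes (default 100, lengths 2,100–2,600 bp, alternating strands, 6 kb
spacing so every gene passes the isolation filter by construction) emit
sense reads whose 5′ end falls in the pause zone (TSS +20..+100) with
condition-specific probability π, else uniformly over the gene span;
antisense (10%) and uniform intergenic (5%) background is added. The
default ages program π = 0.60 / 0.45 / 0.30 for young / middle / aged —
destabilization of pausing with age — while ATAC promoter enrichment rises
2× / 3× / 4× over background. A fifth of the genes additionally change
expression monotonically across ages (alternating up/down, ±1 log2 at the
extreme age) so the differential and trajectory stages have signal to
find. Gene lengths were chosen so that the young-condition standard-window
PI, whose closed form is ((π/(1−π))·L_gene + 201)/401, sits near but
mostly below the extreme-PI cap of 10; the longest young genes exceed the
cap and are removed by the filter, mirroring the small extreme tail such
data produce.

The expected PI of this emission model has the closed form

    E[PI] = ( π·|zone ∩ win|/L_zone + (1−π)·|span ∩ win|/L_gene ) / L_win
            ÷ ( (1−π)/L_gene )

for any measurement window `win` and a body region free of pause signal
(the default geometry); the general form with pause signal in the
denominator is implemented via interval overlaps. The expression was
verified against a 10⁶-read Monte-Carlo simulation (relative deviation
< 0.4%) before being frozen into the tests, which re-verify it at 2×10⁵
reads within 2%.

ATAC fragments draw midpoints from a background + promoter + enhancer
mixture with per-bp weights, and lengths from a two-component normal
(sub-nucleosomal ≈ 60 bp, mono-nucleosomal ≈ 200 bp, sd 15, floor 30).
Peak simulation jitters truth-region edges (sd 20 bp) and drops whole
peaks per replicate with probability 0.1 by default; with dropout 0 the
enhancer caller recovers the truth set exactly, and under dropout the
recall of the all-sample consensus follows the analytic binomial
expectation. NB count matrices use a gamma-Poisson draw with lognormal
region means (mean 100, sd 0.5 on the log), dispersion 0.05, and
programmed log2 fold changes on a stated fraction of regions.

All randomness flows from a single seed through crc32-tagged
`SeedSequence` substreams, so every sample, assay and purpose has an
independent, reproducible stream, and the whole pipeline is byte-identical
across reruns with the same configuration.

## Problem sizes and numerical choices

The packaged demo uses 100 genes × 9 samples × 2,000 sense reads per gene
and 40,000 ATAC fragments per sample; the full pipeline completes in
roughly ten seconds on one CPU, and the statistical calibration runs use
2,000 regions. Tolerances in the test suite: closed-form vs Monte-Carlo
PI at 2% (2×10⁵ draws), empirical PI recovery at 10% median relative
error, type-I error within 0.05 ± 0.02, size-factor recovery within 2%.
Quantile grouping assigns remainder genes to the lowest groups and breaks
value ties by gene id; the metagene bootstrap uses 1,000 seeded percentile
resamples for its 95% band (the band's method is a package choice);
half-up rounding is used for reported percentages.

## Known limitations

* The NB tests deliberately omit dispersion trends, shrinkage toward a
  fitted mean-dispersion curve, and outlier handling; on real data with
  strongly region-dependent dispersion they will be less powerful than
  full-featured packages.
* The 5′ UTR annotation is an exonic-upstream-of-ORF proxy, not a
  transcript-model UTR.
* Genes spanning multiple chromosomes or trans-spliced transcripts are not
  modelled; chromosome-end clipping is handled for windows but genes are
  assumed to fit their chromosome.
* The generator draws non-pause reads uniformly over the gene span; real
  Pol II density has 5′/3′ structure (termination peaks, splicing dwell)
  that the closed-form PI does not capture.
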