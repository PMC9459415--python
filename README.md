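# pausepipe

Integrative analysis of nascent transcription and chromatin accessibility,
built around promoter-proximal RNA polymerase II (Pol II) pausing in aging
tissue. The package is aimed at computational genomicists working with
NET-seq-style nascent transcription data (where the 5′ end of each read marks
the exact genomic position of engaged Pol II) together with ATAC-seq
accessibility data, and provides the full analysis chain as a tested,
reusable library plus CLI:

* **Gene selection** — protein-coding genes longer than 2 kb, isolated by
  2.5 kb from any other transcription unit, with the canonical transcript
  chosen as the longest coding sequence (longest cDNA for non-coding genes),
  then filtered for coverage (RPKM > 1).
* **Nucleotide-resolution density** — strand-aware 5′-end recording of
  alignments into sparse per-base tracks, with RPM (reads per million primary
  aligned), RPKM, and RPGC (1× genome coverage) normalizations.
* **Pausing index** — for each gene and sample,

  `PI = mean sense Pol II density in [TSS − 200, TSS + 200] / mean sense density in [TSS + 200, TES − 200]`

  with an alternative narrow numerator window (TSS +20 to +100 bp, where
  polymerase physically stalls), an extreme-value filter (PI ≤ 10 in all
  samples), pausing categories (high: PI ≥ 3, moderate: 1.5 ≤ PI < 3,
  low: PI < 1.5), per-condition fold changes, and integration with promoter
  accessibility over the identical windows.
* **Consensus peaks and enhancers** — replicate peak sets merged into
  consensus regions supported by ≥ *k* samples; active enhancers called as
  H3K27ac consensus peaks that (i) do not overlap H3K4me3, (ii) lie outside
  TSS ± 1 kb, and (iii) overlap accessible (ATAC) sites; eRNA levels
  quantified as Pol II density over enhancers.
* **Differential statistics** — median-of-ratios size factors; two-group
  negative-binomial Wald test and a multi-condition NB likelihood-ratio test
  with moderated method-of-moments dispersions; Benjamini–Hochberg FDR;
  two-proportion z and Wilcoxon rank-sum tests; Kendall-distance
  (d = 1 − τ) trajectory clustering by divisive hierarchical clustering
  (DIANA); z-scored trajectory profiles.
* **Synthetic data** — a fully seeded generator (annotation, stranded
  Pol II 5′-end reads with a condition-dependent pause zone, paired-end ATAC
  fragments, replicate peak sets with jitter/dropout, NB count matrices)
  whose ground truth includes a closed-form expected pausing index, so every
  stage is testable without downloads.

## Worked example

Run the packaged "aging-demo" scenario — three age groups (young, middle,
aged) × three replicates, 100 genes, 2,000 sense reads per gene, with the
pause weight declining (0.60 → 0.45 → 0.30) and promoter accessibility
rising with age:

```python
from pausepipe import run_pipeline

summary = run_pipeline({"seed": 1, "outdir": "demo_out"})
print(summary["median_pi"])
print(summary["pi_median_relative_error"])
print(summary["quadrant_fractions"])
```

prints

```
{'young': 8.858920558947844, 'middle': 5.165911418092648, 'aged': 2.9473067785473046}
{'young': 0.02167739334954693, 'middle': 0.019715591655063276, 'aged': 0.014433426719013334}
{'acc_up_pi_up': 0.0, 'acc_up_pi_down': 1.0, 'acc_down_pi_up': 0.0, 'acc_down_pi_down': 0.0}
```

The median pausing index falls monotonically across the three ages,
tracking the programmed decline in pause weight; the per-condition median
relative error of the measured PI against the generator's closed-form
expectation is about 2%; and every promoter lands in the
"accessibility up / pausing down" quadrant, the signature of increased
promoter opening with destabilized pausing. `demo_out/` receives the
pausing table, gene-body counts, differential results, enhancer and
consensus BED files, trajectory clusters, and `summary.json`.

The same pipeline is scriptable from the shell:

```
pausepipe simulate --seed 1 --outdir sim           # write GTF/BED/narrowPeak fixtures
pausepipe density sim/tnet_young_r1.bed --out-prefix young_r1   # 5′-end bedGraphs
pausepipe run-all config.json                      # full run from a JSON config
```

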