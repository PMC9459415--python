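"""Synthetic annotation, reads, peaks and count matrices with known truth.

The generator emulates the statistical structure the pipeline assumes:

* a toy genome of well-separated protein-coding genes (> 2 kb, > 5 kb
  apart, alternating strands) so the structural gene filters retain all of
  them by construction;
* stranded single-base Pol II 5'-end emissions: each sense read's 5' end
  falls in the promoter-proximal pause zone (TSS +20..+100 by default) with
  condition-specific probability ``pause_weight``, otherwise uniformly over
  the gene span; antisense and intergenic background reads are added at
  configured rates.  The pause weight declines with age in the packaged
  "aging-demo" scenario, mimicking destabilization of the pausing complex;
* unstranded ATAC cut sites from a background + promoter/enhancer-enriched
  mixture with two-component fragment lengths (sub- and mono-nucleosomal);
  promoter enrichment rises with age;
* replicate narrowPeak sets for H3K27ac / H3K4me3 / ATAC with edge jitter
  and per-replicate dropout, plus decoy H3K27ac peaks lacking ATAC support;
* negative-binomial count matrices with programmed per-sample size
  multipliers and true log2 fold changes.

Every quantity carries a closed-form expectation in the truth tables; in
particular the expected pausing index of a gene with pause weight ``pi`` is

    PI = [ pi * |zone ∩ win| / L_zone  +  (1 - pi) * |span ∩ win| / L_gene ]
         / L_win  /  [ (1 - pi) / L_gene ]

for a measurement window ``win`` containing no pause signal in the body
denominator (the default geometry), verified against a Monte-Carlo oracle.
All randomness flows from one seed through deterministic per-sample
substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .density import AlignmentRecord
from .diffstats import CountMatrix
from .peaks import PeakSet
from .regions import GeneModel, GeneSet, GenomicInterval, gene_body_region, narrow_pause_window, promoter_window


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition emission parameters."""

    pause_weight: float = 0.6          # probability a sense 5' end is in the pause zone
    reads_per_gene: float = 2000.0     # Poisson mean of sense reads per gene
    atac_promoter_enrichment: float = 2.0  # per-bp rate multiplier at promoters


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults describe the packaged "aging-demo" scenario: three age groups
    with three replicates each, promoter accessibility rising and pause
    weight falling with age, on a two-chromosome toy genome of 100 genes.
    """

    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (2100, 2600)
    gene_spacing: int = 6000           # > 5 kb so every gene passes isolation
    read_length: int = 50
    pause_zone: str = "narrow"         # 'narrow' = TSS+20..+100; 'promoter' = TSS+/-200
    antisense_fraction: float = 0.10
    intergenic_noise_rate: float = 0.05
    # programmed expression trajectories: the first
    # expression_effect_fraction of genes change monotonically across the
    # ordered conditions, alternating up/down, reaching +/- the stated
    # log2FC in the last condition
    expression_effect_fraction: float = 0.2
    expression_effect_log2fc: float = 1.0
    n_replicates: int = 3
    conditions: dict[str, ConditionParams] = field(
        default_factory=lambda: {
            "young": ConditionParams(0.60, 2000.0, 2.0),
            "middle": ConditionParams(0.45, 2000.0, 3.0),
            "aged": ConditionParams(0.30, 2000.0, 4.0),
        }
    )
    # enhancers
    n_enhancers: int = 30
    enhancer_width: int = 600
    enhancer_active_fraction: float = 0.7
    erna_reads_per_enhancer: float = 120.0
    n_decoy_peaks: int = 10
    # ATAC
    atac_fragments_per_sample: int = 40000
    atac_enhancer_enrichment: float = 3.0
    fragment_length_means: tuple[float, float] = (60.0, 200.0)
    fragment_length_sd: float = 15.0
    subnucleosomal_fraction: float = 0.5
    # peak simulation
    peak_jitter_sd: float = 20.0
    peak_dropout: float = 0.1
    promoter_peak_half_width: int = 300
    # NB count matrix
    nb_n_regions: int = 2000
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    nb_effect_fraction: float = 0.1
    nb_effect_log2fc: float = 1.0
    nb_size_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        per_chrom = self._genes_per_chrom()
        slot = self.gene_spacing + self.gene_length_range[1]
        return {
            f"chr{i + 1}": (per_chrom[i] + 1) * slot + self.gene_spacing
            for i in range(self.n_chroms)
        }

    def _genes_per_chrom(self) -> list[int]:
        base, rem = divmod(self.n_genes, self.n_chroms)
        return [base + (1 if i < rem else 0) for i in range(self.n_chroms)]

    @property
    def effective_genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def sample_names(self) -> list[tuple[str, str]]:
        return [
            (cond, f"{cond}_r{r + 1}")
            for cond in self.conditions
            for r in range(self.n_replicates)
        ]


def _substream(config: SyntheticConfig, *tags: str) -> np.random.Generator:
    """Deterministic per-purpose RNG derived from the run seed.

    Tags are digested with crc32 (process-stable, unlike ``hash``)."""
    import zlib

    entropy = [config.seed] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SyntheticConfig) -> tuple[list[GeneModel], GeneSet]:
    """Place genes on the toy genome; returns (genes, truth GeneSet).

    Genes alternate strand along each chromosome and are separated by
    ``gene_spacing`` bp, so the truth GeneSet simply retains all of them.
    """
    rng = _substream(config, "annotation")
    genes: list[GeneModel] = []
    per_chrom = config._genes_per_chrom()
    slot = config.gene_spacing + config.gene_length_range[1]
    idx = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for gi in range(per_chrom[ci]):
            length = int(rng.integers(*config.gene_length_range))
            left = (gi + 1) * slot
            right = left + length
            if right > config.chrom_lengths[chrom]:
                raise ValueError("gene does not fit chromosome")
            strand = "+" if idx % 2 == 0 else "-"
            tss, tes = (left, right) if strand == "+" else (right, left)
            gene = GeneModel(
                gene_id=f"G{idx:04d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                tes=tes,
                biotype="protein_coding",
                exons=[GenomicInterval(chrom, left, right, strand)],
                canonical_transcript_id=f"T{idx:04d}",
            )
            genes.append(gene)
            idx += 1
    return genes, GeneSet(genes=list(genes), selection_log={})


def write_gtf(genes: list[GeneModel], path: str) -> None:
    """Write the toy annotation as Ensembl-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            left, right = g.span_start + 1, g.span_end  # to 1-based closed
            attrs_gene = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            attrs_tx = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.canonical_transcript_id}"; '
                f'gene_biotype "{g.biotype}";'
            )
            for feature, attr in (
                ("gene", attrs_gene),
                ("transcript", attrs_tx),
                ("exon", attrs_tx),
                ("CDS", attrs_tx),
            ):
                fh.write(
                    f"{g.chrom}\tsim\t{feature}\t{left}\t{right}\t.\t{g.strand}\t.\t{attr}\n"
                )


def write_chrom_sizes(config: SyntheticConfig, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def simulate_enhancers(
    config: SyntheticConfig, genes: list[GeneModel]
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Truth enhancers placed mid-gap between genes, > 1 kb from every TSS."""
    rng = _substream(config, "enhancers")
    gaps: list[GenomicInterval] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.span_start)
        for a, b in zip(glist, glist[1:]):
            gap_start = a.span_end + 1500  # clear of TSS +/- 1 kb windows
            gap_end = b.span_start - 1500
            if gap_end - gap_start > config.enhancer_width + 200:
                gaps.append(GenomicInterval(chrom, gap_start, gap_end, "."))
    if len(gaps) < config.n_enhancers:
        raise ValueError("not enough intergenic space for requested enhancers")
    chosen = rng.choice(len(gaps), size=config.n_enhancers, replace=False)
    enhancers, records = [], []
    for rank, gi in enumerate(sorted(chosen)):
        gap = gaps[gi]
        start = int(rng.integers(gap.start, gap.end - config.enhancer_width))
        e = GenomicInterval(gap.chrom, start, start + config.enhancer_width, ".")
        active = bool(rng.random() < config.enhancer_active_fraction)
        enhancers.append(e)
        records.append(
            {
                "enhancer_id": f"E{rank:03d}",
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "active": active,
            }
        )
    return enhancers, pd.DataFrame.from_records(records).set_index("enhancer_id")


# ---------------------------------------------------------------------------
# Closed-form expected PI
# ---------------------------------------------------------------------------

def _zone(gene: GeneModel, config: SyntheticConfig) -> GenomicInterval:
    if config.pause_zone == "narrow":
        return narrow_pause_window(gene)
    return promoter_window(gene)


def _olap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def expected_pausing_index(
    gene: GeneModel, pause_weight: float, config: SyntheticConfig, window: str = "standard"
) -> float:
    """Analytic PI for the two-component emission model.

    A sense 5' end lands uniformly in the pause zone with probability
    ``pause_weight``, else uniformly over the gene span.  The expected mean
    density of a measurement region R is then

        E[mean(R)] = N * [ pi * |zone∩R| / L_zone + (1-pi) * |span∩R| / L_span ] / |R|

    and the PI is the ratio of this expectation over the promoter window to
    that over the body region.
    """
    zone = _zone(gene, config)
    span = gene.span
    win = promoter_window(gene) if window == "standard" else narrow_pause_window(gene)
    body = gene_body_region(gene)
    pi = pause_weight

    def mean_density(region: GenomicInterval) -> float:
        return (
            pi * _olap(zone, region) / len(zone)
            + (1 - pi) * _olap(span, region) / len(span)
        ) / len(region)

    num = mean_density(win)
    den = mean_density(body)
    if den == 0:
        raise ValueError("expected body density is zero")
    return num / den


# ---------------------------------------------------------------------------
# tNET-seq reads
# ---------------------------------------------------------------------------

def _records_from_five_prime(
    chrom: str, positions: np.ndarray, strand: str, read_length: int, chrom_len: int
) -> list[AlignmentRecord]:
    recs = []
    for p in positions:
        p = int(p)
        if strand == "+":
            start, end = p, min(p + read_length, chrom_len)
        else:
            start, end = max(p - read_length + 1, 0), p + 1
        recs.append(AlignmentRecord(chrom, start, end, strand, mapq=60))
    return recs


def simulate_tnet_reads(
    config: SyntheticConfig,
    condition: str,
    replicate: int,
    genes: list[GeneModel],
    enhancers: pd.DataFrame | None = None,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Simulate one tNET-seq library; returns (records, per-gene truth).

    Truth columns: n_sense_reads, pause_weight, expected_pi (standard
    window) and expected_pi_narrow.
    """
    params = config.conditions[condition]
    rng = _substream(config, "tnet", condition, f"r{replicate}")
    records: list[AlignmentRecord] = []
    truth_rows = []
    chrom_lengths = config.chrom_lengths

    cond_names = list(config.conditions)
    stage = cond_names.index(condition) / max(len(cond_names) - 1, 1)
    n_effect = int(round(config.expression_effect_fraction * len(genes)))

    for gi, gene in enumerate(genes):
        if gi < n_effect:
            sign = 1.0 if gi % 2 == 0 else -1.0
            multiplier = 2.0 ** (sign * config.expression_effect_log2fc * stage)
        else:
            multiplier = 1.0
        n = int(rng.poisson(params.reads_per_gene * multiplier))
        zone = _zone(gene, config)
        in_zone = rng.random(n) < params.pause_weight
        pos = np.empty(n, dtype=np.int64)
        pos[in_zone] = rng.integers(zone.start, zone.end, size=int(in_zone.sum()))
        pos[~in_zone] = rng.integers(
            gene.span_start, gene.span_end, size=int((~in_zone).sum())
        )
        records.extend(
            _records_from_five_prime(
                gene.chrom, pos, gene.strand, config.read_length, chrom_lengths[gene.chrom]
            )
        )
        # antisense background uniform over the span, opposite strand
        n_anti = int(rng.poisson(config.antisense_fraction * params.reads_per_gene))
        anti_pos = rng.integers(gene.span_start, gene.span_end, size=n_anti)
        anti_strand = "-" if gene.strand == "+" else "+"
        records.extend(
            _records_from_five_prime(
                gene.chrom, anti_pos, anti_strand, config.read_length,
                chrom_lengths[gene.chrom],
            )
        )
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "n_sense_reads": n,
                "expression_multiplier": multiplier,
                "pause_weight": params.pause_weight,
                "expected_pi": expected_pausing_index(
                    gene, params.pause_weight, config, "standard"
                ),
                "expected_pi_narrow": expected_pausing_index(
                    gene, params.pause_weight, config, "narrow"
                ),
            }
        )

    # eRNA emission at active truth enhancers (both strands)
    if enhancers is not None:
        for _eid, row in enhancers.iterrows():
            if not row["active"]:
                continue
            n_e = int(rng.poisson(config.erna_reads_per_enhancer))
            pos = rng.integers(row["start"], row["end"], size=n_e)
            strands = rng.random(n_e) < 0.5
            for p, plus in zip(pos, strands):
                s = "+" if plus else "-"
                records.extend(
                    _records_from_five_prime(
                        row["chrom"], np.array([p]), s, config.read_length,
                        chrom_lengths[row["chrom"]],
                    )
                )

    # intergenic noise, uniform over the genome, random strand
    total_gene_reads = len(genes) * params.reads_per_gene
    n_noise = int(rng.poisson(config.intergenic_noise_rate * total_gene_reads))
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_noise, p=lengths / lengths.sum())
    for ci in chrom_idx:
        p = int(rng.integers(0, chrom_lengths[chroms[ci]] - config.read_length))
        s = "+" if rng.random() < 0.5 else "-"
        records.extend(
            _records_from_five_prime(
                chroms[ci], np.array([p]), s, config.read_length, chrom_lengths[chroms[ci]]
            )
        )

    truth = pd.DataFrame.from_records(truth_rows).set_index("gene_id")
    return records, truth


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------

def simulate_atac(
    config: SyntheticConfig,
    condition: str,
    replicate: int,
    genes: list[GeneModel],
    enhancers: pd.DataFrame | None = None,
) -> tuple[list[AlignmentRecord], list[GenomicInterval]]:
    """Simulate one paired-end ATAC library.

    Fragment midpoints are drawn from a mixture: uniform background, plus
    promoter windows weighted by the condition's enrichment factor and
    enhancers by ``atac_enhancer_enrichment``.  Fragment lengths come from
    the sub-/mono-nucleosomal two-component distribution.  Returns (paired
    read records, fragments).
    """
    params = config.conditions[condition]
    rng = _substream(config, "atac", condition, f"r{replicate}")
    chrom_lengths = config.chrom_lengths
    chroms = list(chrom_lengths)

    # sampling components: (chrom, start, end, weight-per-bp)
    comps: list[tuple[str, int, int, float]] = []
    for c in chroms:
        comps.append((c, 0, chrom_lengths[c], 1.0))
    for g in genes:
        w = promoter_window(g)
        comps.append((w.chrom, w.start, w.end, params.atac_promoter_enrichment - 1.0))
    if enhancers is not None:
        for _eid, row in enhancers.iterrows():
            comps.append(
                (row["chrom"], row["start"], row["end"], config.atac_enhancer_enrichment - 1.0)
            )
    weights = np.array([(e - s) * w for _c, s, e, w in comps], dtype=float)
    probs = weights / weights.sum()

    n = config.atac_fragments_per_sample
    comp_idx = rng.choice(len(comps), size=n, p=probs)
    sub = rng.random(n) < config.subnucleosomal_fraction
    mean_len = np.where(sub, config.fragment_length_means[0], config.fragment_length_means[1])
    frag_len = np.maximum(
        rng.normal(mean_len, config.fragment_length_sd).round().astype(int), 30
    )

    read_len = min(config.read_length, 36)
    fragments: list[GenomicInterval] = []
    records: list[AlignmentRecord] = []
    for i in range(n):
        c, s, e, _w = comps[comp_idx[i]]
        mid = int(rng.integers(s, e))
        half = int(frag_len[i]) // 2
        fs = max(0, mid - half)
        fe = min(chrom_lengths[c], fs + int(frag_len[i]))
        if fe - fs < 2 * 1:
            continue
        fragments.append(GenomicInterval(c, fs, fe, "."))
        rl = min(read_len, fe - fs)
        records.append(AlignmentRecord(c, fs, fs + rl, "+", mapq=60, is_proper_pair=True))
        records.append(AlignmentRecord(c, fe - rl, fe, "-", mapq=60, is_proper_pair=True))
    return records, fragments


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

def _jittered_peak(
    iv: GenomicInterval, rng: np.random.Generator, sd: float, chrom_len: int
) -> GenomicInterval:
    start = int(round(iv.start + rng.normal(0, sd)))
    end = int(round(iv.end + rng.normal(0, sd)))
    start = max(0, start)
    end = min(chrom_len, max(end, start + 50))
    return GenomicInterval(iv.chrom, start, end, ".")


def simulate_peak_sets(
    config: SyntheticConfig,
    genes: list[GeneModel],
    enhancers: pd.DataFrame,
    n_replicates: int | None = None,
    dropout: float | None = None,
) -> dict[str, list[PeakSet]]:
    """Replicate peak sets for H3K27ac, H3K4me3 and ATAC.

    Truth enhancers emit K27ac + ATAC peaks; promoters emit K27ac + K4me3 +
    ATAC peaks; decoy K27ac peaks (no ATAC support, intergenic) are added.
    Edges are jittered per replicate; whole peaks drop out with probability
    ``dropout``.
    """
    n_reps = n_replicates if n_replicates is not None else config.n_replicates
    drop = dropout if dropout is not None else config.peak_dropout
    rng = _substream(config, "peaks")
    chrom_lengths = config.chrom_lengths

    enhancer_ivs = [
        GenomicInterval(row["chrom"], row["start"], row["end"], ".")
        for _e, row in enhancers.iterrows()
    ]
    promoter_ivs = [
        GenomicInterval(
            g.chrom,
            max(0, g.tss - config.promoter_peak_half_width),
            g.tss + config.promoter_peak_half_width,
            ".",
        )
        for g in genes
    ]
    # decoys: intergenic K27ac without ATAC, midway into large gaps but
    # clear of enhancers and TSS windows
    decoys: list[GenomicInterval] = []
    rng_d = _substream(config, "decoys")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    taken = {(e.chrom, e.start // 1000) for e in enhancer_ivs}
    for chrom, glist in sorted(by_chrom.items()):
        glist.sort(key=lambda g: g.span_start)
        for a, b in zip(glist, glist[1:]):
            if len(decoys) >= config.n_decoy_peaks:
                break
            gap_start, gap_end = a.span_end + 1500, b.span_start - 1500
            if gap_end - gap_start < 800:
                continue
            start = int(rng_d.integers(gap_start, gap_end - 400))
            if (chrom, start // 1000) in taken or (chrom, start // 1000 + 1) in taken:
                continue
            cand = GenomicInterval(chrom, start, start + 400, ".")
            if any(cand.overlaps(e) for e in enhancer_ivs):
                continue
            decoys.append(cand)

    sources = {
        "H3K27ac": enhancer_ivs + promoter_ivs + decoys,
        "H3K4me3": promoter_ivs,
        "ATAC": enhancer_ivs + promoter_ivs,
    }
    out: dict[str, list[PeakSet]] = {}
    for assay, ivs in sources.items():
        sets = []
        for r in range(n_reps):
            peaks = []
            for iv in ivs:
                if rng.random() < drop:
                    continue
                peaks.append(
                    _jittered_peak(iv, rng, config.peak_jitter_sd, chrom_lengths[iv.chrom])
                )
            sets.append(PeakSet(peaks=peaks, sample_id=f"{assay}_r{r + 1}"))
        out[assay] = sets
    return out


def write_narrowpeak(peak_set: PeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peak_set.peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t0\t-1\t-1\t{len(p) // 2}\n"
            )


# ---------------------------------------------------------------------------
# NB count matrix
# ---------------------------------------------------------------------------

def simulate_count_matrix(
    config: SyntheticConfig,
    n_conditions: int = 2,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts with programmed effects and size multipliers.

    The first ``nb_effect_fraction`` of regions carry a true log2FC of
    ``nb_effect_log2fc`` in every non-reference condition (alternating
    sign).  Size multipliers apply per sample in column order.  Returns
    (CountMatrix, truth with true_log2fc per region).
    """
    rng = _substream(config, "counts")
    n_regions = config.nb_n_regions
    reps = config.n_replicates
    conds = [f"c{i + 1}" for i in range(n_conditions)]
    samples = [(c, f"{c}_r{r + 1}") for c in conds for r in range(reps)]
    mults = list(config.nb_size_multipliers)
    if len(mults) < len(samples):
        mults = (mults * len(samples))[: len(samples)]

    n_effect = int(round(config.nb_effect_fraction * n_regions))
    true_lfc = np.zeros(n_regions)
    signs = np.where(np.arange(n_effect) % 2 == 0, 1.0, -1.0)
    true_lfc[:n_effect] = signs * config.nb_effect_log2fc

    base_mean = config.nb_mean * np.exp(rng.normal(0, 0.5, size=n_regions))
    alpha = config.nb_dispersion
    cols = {}
    for j, (cond, sample) in enumerate(samples):
        mu = base_mean * mults[j]
        if cond != conds[0]:
            mu = mu * 2.0**true_lfc
        if alpha > 0:
            lam = rng.gamma(shape=1 / alpha, scale=mu * alpha)
        else:
            lam = mu
        cols[sample] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=[f"region_{i:05d}" for i in range(n_regions)])
    matrix = CountMatrix(counts=counts, conditions={s: c for c, s in samples})
    truth = pd.DataFrame(
        {"true_log2fc": true_lfc, "base_mean": base_mean}, index=counts.index
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def aging_demo_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The packaged aging-demo scenario: young/middle/aged x 3 replicates,
    accessibility up and pausing down with age."""
    return replace(SyntheticConfig(seed=seed), **overrides)
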