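"""Metagene matrices, proportion summaries and the end-to-end pipeline run.

``metagene_matrix`` extracts 1x-normalized signal around a set of anchors
(typically TSSs), orienting minus-strand rows so transcription always runs
left to right, and summarises the column means with a percentile-bootstrap
95% band.  ``proportion_report`` turns labeled count pairs into the
machine-readable percentage table the pipeline reports.  ``run_pipeline``
executes the whole analysis on a synthetic scenario with known truth:
annotation -> density -> pausing -> enhancers -> differential ->
trajectory clustering -> summary JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import diffstats, pausing, peaks, regions, simulate
from .density import (
    DensityTrack,
    atac_cut_sites,
    build_density,
    count_primary_aligned,
    filter_alignments,
    five_prime_positions,
    rpgc_normalize,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metagene
# ---------------------------------------------------------------------------

def metagene_matrix(
    track: DensityTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    binsize: int = 1,
    strand_mode: str = "both",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signal matrix around anchors plus a bootstrapped mean profile.

    Each row covers [anchor - flank, anchor + flank), averaged into bins of
    ``binsize`` bp and reversed for minus-strand anchors so transcription
    runs left to right.  Anchors closer than ``flank`` to the chromosome
    start get NaN padding.  Returns (matrix, profile) where profile holds
    the column mean with a percentile-bootstrap 95% band over anchors.
    """
    if flank < binsize:
        raise ValueError("flank must be >= binsize")
    n_bins = (2 * flank) // binsize
    rows = []
    for chrom, pos, strand in anchors:
        start, end = pos - flank, pos + flank
        pad_left = max(0, -start)
        window = track.region_window(
            chrom, max(start, 0), end, strand=strand if strand_mode == "sense" else "."
        )
        if pad_left:
            logger.info("anchor %s:%d within flank of chromosome start; padded", chrom, pos)
            window = np.concatenate([np.full(pad_left, np.nan), window])
        binned = window[: n_bins * binsize].reshape(n_bins, binsize).mean(axis=1)
        if strand == "-":
            binned = binned[::-1]
        rows.append(binned)
    offsets = np.arange(-flank, flank, binsize)
    matrix = pd.DataFrame(rows, columns=offsets)

    values = matrix.values
    rng = np.random.default_rng(seed)
    n = len(matrix)
    boot = np.empty((n_bootstrap, n_bins))
    with warnings.catch_warnings():
        # edge-padded columns can be all-NaN in a resample; NaN is the
        # correct result there
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boot[b] = np.nanmean(values[idx], axis=0)
        lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    profile = pd.DataFrame({"mean": mean, "ci_low": lo, "ci_high": hi}, index=offsets)
    return matrix, profile


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def _round_half_up(value: float, digits: int) -> float:
    factor = 10.0**digits
    return np.floor(value * factor + 0.5) / factor


def proportion_report(
    items: Sequence[tuple[str, int, int] | tuple[str, int, int, int]],
) -> pd.DataFrame:
    """Percentages from labeled (numerator, denominator[, precision]) triples.

    Percentage = 100 * num / den, rounded half-up at the stated precision
    (default 1 decimal).
    """
    records = []
    for item in items:
        label, num, den = item[0], item[1], item[2]
        precision = item[3] if len(item) > 3 else 1
        if den <= 0:
            raise ValueError(f"{label}: zero denominator")
        records.append(
            {
                "label": label,
                "numerator": num,
                "denominator": den,
                "percentage": _round_half_up(100.0 * num / den, precision),
                "precision": precision,
            }
        )
    return pd.DataFrame.from_records(records).set_index("label")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"scenario", "seed", "outdir", "fdr", "pi_cap", "overrides", "write_outputs"}


def run_pipeline(config: dict) -> dict:
    """Run the full analysis on the synthetic aging scenario.

    ``config`` keys: ``scenario`` ('aging-demo'), ``seed``, optional
    ``outdir`` (TSV/BED/JSON outputs), ``fdr`` (default 0.05), ``pi_cap``
    (default 10), ``overrides`` (SyntheticConfig field overrides) and
    ``write_outputs``.  Unknown keys raise a validation error naming the
    key.  Returns the summary dictionary (also written as summary.json).
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    scenario = config.get("scenario", "aging-demo")
    if scenario != "aging-demo":
        raise ValueError(f"unknown scenario {scenario!r}")
    seed = int(config.get("seed", 0))
    fdr = float(config.get("fdr", 0.05))
    pi_cap = float(config.get("pi_cap", 10.0))
    overrides = dict(config.get("overrides", {}))
    outdir = Path(config["outdir"]) if "outdir" in config else None
    write_outputs = bool(config.get("write_outputs", outdir is not None))

    sim_cfg = simulate.aging_demo_config(seed=seed, **overrides)
    summary: dict = {"scenario": scenario, "seed": seed, "config": _jsonable(asdict(sim_cfg))}

    # --- annotation and gene selection -------------------------------------
    genes, _truth_set = simulate.simulate_annotation(sim_cfg)
    gene_set = regions.select_tnet_genes(genes)
    enhancer_ivs, enhancer_truth = simulate.simulate_enhancers(sim_cfg, genes)
    summary["n_genes_annotated"] = len(genes)
    summary["n_genes_selected"] = len(gene_set)

    # --- tNET-seq densities and pausing -------------------------------------
    tracks: dict[str, DensityTrack] = {}
    truth_by_cond: dict[str, pd.DataFrame] = {}
    for cond, sample in sim_cfg.sample_names():
        rep = int(sample.rsplit("r", 1)[1])
        records, truth = simulate.simulate_tnet_reads(
            sim_cfg, cond, rep, genes, enhancer_truth
        )
        truth_by_cond.setdefault(cond, truth)
        lib = count_primary_aligned(records)
        positions = five_prime_positions(filter_alignments(records))
        tracks[sample] = build_density(positions, lib, mode="RPM")

    sample_conditions = {s: c for c, s in sim_cfg.sample_names()}
    pi_table = pausing.compute_pi_table(tracks, gene_set, window="standard")
    pi_capped = pausing.filter_extreme_pi(pi_table, cap=pi_cap)
    summary["n_genes_pi"] = len(pi_table)
    summary["n_genes_pi_capped"] = len(pi_capped)

    cond_pi = pausing.condition_mean_pi(pi_capped, sample_conditions)
    summary["median_pi"] = {c: float(cond_pi[c].median()) for c in cond_pi.columns}

    cond_pi_all = pausing.condition_mean_pi(pi_table, sample_conditions)
    rel_err = {}
    for cond in cond_pi_all.columns:
        expected = truth_by_cond[cond]["expected_pi"].reindex(cond_pi_all.index)
        rel = ((cond_pi_all[cond] - expected) / expected).abs()
        rel_err[cond] = float(rel.median())
    summary["pi_median_relative_error"] = rel_err

    narrow_table = pausing.compute_pi_table(tracks, gene_set, window="narrow")
    cond_narrow = pausing.condition_mean_pi(narrow_table, sample_conditions)
    summary["median_pi_narrow"] = {
        c: float(cond_narrow[c].median()) for c in cond_narrow.columns
    }

    pi_fc = pausing.pi_fold_change(pi_capped, sample_conditions, ("young", "aged"))
    summary["median_pi_log2fc_aged_vs_young"] = float(pi_fc.median())

    young_pis = cond_pi["young"]
    categories = young_pis.map(pausing.classify_pausing)
    cat_counts = categories.value_counts().to_dict()
    summary["pausing_categories_young"] = {
        k: int(cat_counts.get(k, 0)) for k in ("high", "moderate", "low")
    }
    n_cat = len(categories)
    summary["pct_paused_young"] = float(
        _round_half_up(
            100.0 * (cat_counts.get("high", 0) + cat_counts.get("moderate", 0)) / n_cat, 1
        )
    )

    # --- ATAC accessibility --------------------------------------------------
    atac_tracks: dict[str, DensityTrack] = {}
    atac_fragments: dict[str, list] = {}
    for cond, sample in sim_cfg.sample_names():
        rep = int(sample.rsplit("r", 1)[1])
        records, fragments = simulate.simulate_atac(
            sim_cfg, cond, rep, genes, enhancer_truth
        )
        lib = count_primary_aligned(records)
        sites = atac_cut_sites(filter_alignments(records))
        atac_tracks[sample] = build_density(sites, lib, mode="RPM")
        atac_fragments[sample] = fragments

    promoters = {g.gene_id: regions.promoter_window(g) for g in gene_set.genes}
    acc = pd.DataFrame(
        {
            sample: {
                gid: track.region_sum(win) / len(win) for gid, win in promoters.items()
            }
            for sample, track in atac_tracks.items()
        }
    )
    acc_cond = pd.DataFrame(
        {
            cond: acc[[s for s, c in sample_conditions.items() if c == cond]].mean(axis=1)
            for cond in sim_cfg.conditions
        }
    )
    valid = (acc_cond["young"] > 0) & (acc_cond["aged"] > 0)
    acc_fc = np.log2(acc_cond.loc[valid, "aged"] / acc_cond.loc[valid, "young"])
    _joined, quadrants = pausing.integrate_pi_accessibility(pi_fc, acc_fc)
    summary["quadrant_fractions"] = {
        f"acc_{row.accessibility}_pi_{row.pausing}": float(row.fraction)
        for row in quadrants.itertuples()
    }
    summary["median_promoter_acc_log2fc_aged_vs_young"] = float(acc_fc.median())

    # --- peaks and enhancers -------------------------------------------------
    peak_sets = simulate.simulate_peak_sets(sim_cfg, genes, enhancer_truth)
    n_samples = len(peak_sets["H3K27ac"])
    cons = {
        assay: peaks.consensus_peaks(sets, min_support=n_samples)
        for assay, sets in peak_sets.items()
    }
    enhancer_set = peaks.identify_enhancers(
        cons["H3K27ac"], cons["H3K4me3"], cons["ATAC"], genes
    )
    truth_ivs = [
        regions.GenomicInterval(r["chrom"], r["start"], r["end"], ".")
        for _e, r in enhancer_truth.iterrows()
    ]
    if enhancer_set.enhancers:
        n_hit, recall = peaks.overlap_fraction(truth_ivs, enhancer_set.enhancers)
    else:
        n_hit, recall = 0, 0.0
    summary["n_enhancers_called"] = len(enhancer_set)
    summary["n_truth_enhancers"] = len(truth_ivs)
    summary["enhancer_recall"] = float(recall)

    merged_young = _merge_tracks([t for s, t in tracks.items() if s.startswith("young")])
    if enhancer_set.enhancers:
        erna = peaks.erna_level(merged_young, enhancer_set)
        summary["median_erna_density_young"] = float(erna.median())

    # --- differential transcription and trajectories ------------------------
    bodies = [regions.gene_body_region(g) for g in gene_set.genes]
    body_ids = gene_set.gene_ids()
    raw_tracks = {s: t.scaled(1.0 / t.scale) for s, t in tracks.items()}
    matrix = diffstats.count_reads_in_regions(
        raw_tracks, bodies, body_ids, sample_conditions, mode="five_prime_sense"
    )
    size_factors = diffstats.median_of_ratios(matrix)
    wald = diffstats.nb_wald_test(matrix, ("young", "aged"), size_factors, fdr=fdr)
    lrt = diffstats.nb_lrt_test(matrix, size_factors, fdr=fdr)
    summary["n_diff_transcribed_wald"] = int(wald["significant"].sum())
    summary["n_diff_transcribed_lrt"] = int(lrt["significant"].sum())

    sig_ids = lrt.index[lrt["significant"]]
    norm = np.log2(matrix.counts / size_factors + 1.0)
    cond_profiles = pd.DataFrame(
        {
            cond: norm[[s for s, c in sample_conditions.items() if c == cond]].mean(axis=1)
            for cond in sim_cfg.conditions
        }
    ).loc[sig_ids]
    if len(cond_profiles) >= 4:
        dist = diffstats.kendall_distance_matrix(cond_profiles)
        k = min(4, len(dist))
        clusters = diffstats.diana_clustering(dist, k=k)
        summary["trajectory_cluster_sizes"] = {
            str(label): int(n) for label, n in clusters.value_counts().sort_index().items()
        }
        zprofiles = diffstats.zscore_profiles(cond_profiles)
    else:
        clusters, zprofiles = None, None
        summary["trajectory_cluster_sizes"] = {}

    # --- outputs -------------------------------------------------------------
    if write_outputs and outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        pi_capped.to_csv(outdir / "pausing_table.tsv", sep="\t")
        matrix.counts.to_csv(outdir / "gene_body_counts.tsv", sep="\t")
        wald.to_csv(outdir / "differential_wald_aged_vs_young.tsv", sep="\t")
        lrt.to_csv(outdir / "differential_lrt.tsv", sep="\t")
        peaks.write_enhancer_bed(enhancer_set, str(outdir / "enhancers.bed"))
        for assay, c in cons.items():
            peaks.write_consensus_bed(c, str(outdir / f"consensus_{assay}.bed"))
        if clusters is not None:
            pd.DataFrame({"cluster": clusters}).join(zprofiles).to_csv(
                outdir / "trajectory_clusters.tsv", sep="\t"
            )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary


def _merge_tracks(tracks: list[DensityTrack]) -> DensityTrack:
    """Sum several tracks position-wise (same scale assumed)."""
    keys = {k for t in tracks for k in t.data}
    data = {}
    for key in keys:
        pos_all = np.concatenate([t.data[key][0] for t in tracks if key in t.data])
        val_all = np.concatenate([t.data[key][1] for t in tracks if key in t.data])
        order = np.argsort(pos_all, kind="stable")
        pos_sorted, val_sorted = pos_all[order], val_all[order]
        uniq, inverse = np.unique(pos_sorted, return_inverse=True)
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, val_sorted)
        data[key] = (uniq, summed)
    return DensityTrack(
        data=data,
        scale=tracks[0].scale,
        library_size=sum(t.library_size for t in tracks),
        stranded=tracks[0].stranded,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
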