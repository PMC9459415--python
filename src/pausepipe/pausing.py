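"""Promoter-proximal Pol II pausing index (PI) analysis.

The pausing index of a gene is the ratio of mean sense-strand Pol II density
in the promoter-proximal window (TSS +/- 200 bp, or the narrow TSS +20..+100
pause zone) to the mean density in the gene body (TSS +200 to TES -200).
PI > 1 indicates accumulation of polymerase near the promoter relative to
productive elongation; PI declines when the pausing complex destabilizes.

Genes with zero body signal in any sample are excluded (their PI is
undefined), and genes with PI > 10 in any sample are removed as extreme.
Genes are classified as highly (PI >= 3), moderately (1.5 <= PI < 3) or
lowly (PI < 1.5) paused.  The alternative, boundary-inclusive-low convention
(low: PI <= 1.5) is available via ``low_inclusive=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .density import DensityTrack, region_mean_density
from .regions import GeneSet, gene_body_region, narrow_pause_window, promoter_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PausingCategory:
    high_min: float = 3.0
    low_max: float = 1.5
    low_inclusive: bool = False  # True: PI == low_max classified low


def pausing_index(promoter_mean: float, body_mean: float) -> float:
    """PI = promoter mean density / body mean density (body_mean > 0)."""
    if body_mean <= 0:
        raise ValueError("pausing index undefined for zero body density")
    return promoter_mean / body_mean


def compute_pi_table(
    tracks: Mapping[str, DensityTrack],
    gene_set: GeneSet,
    window: str = "standard",
    promoter_half_width: int = 200,
    body_trim: int = 200,
) -> pd.DataFrame:
    """Per-gene, per-sample pausing indices from RPM tracks.

    ``window='standard'`` uses the TSS +/- ``promoter_half_width`` promoter;
    ``window='narrow'`` the TSS +20..+100 pause zone.  Only sense-strand
    signal enters both numerator and denominator.  Genes with zero body
    signal in any sample are dropped and logged.

    Returns a DataFrame indexed by gene_id with columns
    ``promoter_mean_<sample>``, ``body_mean_<sample>``, ``PI_<sample>``.
    """
    if window not in ("standard", "narrow"):
        raise ValueError(f"unknown window {window!r}")
    samples = list(tracks)
    rows = {}
    n_dropped = 0
    for gene in gene_set.genes:
        if window == "standard":
            prom = promoter_window(gene, half_width=promoter_half_width)
        else:
            prom = narrow_pause_window(gene)
        body = gene_body_region(gene, trim=body_trim)
        row: dict[str, float] = {}
        ok = True
        for sample in samples:
            track = tracks[sample]
            pm = region_mean_density(track, prom, "sense")
            bm = region_mean_density(track, body, "sense")
            if bm <= 0:
                ok = False
                break
            row[f"promoter_mean_{sample}"] = pm
            row[f"body_mean_{sample}"] = bm
            row[f"PI_{sample}"] = pausing_index(pm, bm)
        if ok:
            rows[gene.gene_id] = row
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("compute_pi_table: %d genes dropped (zero sense body signal)", n_dropped)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return table


def pi_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("PI_")]


def filter_extreme_pi(table: pd.DataFrame, cap: float = 10.0) -> pd.DataFrame:
    """Remove genes whose PI exceeds ``cap`` in at least one sample."""
    cols = pi_columns(table)
    if not cols:
        raise ValueError("table has no PI columns")
    keep = (table[cols] <= cap).all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_extreme_pi: %d genes removed (PI > %g)", n_removed, cap)
    return table.loc[keep].copy()


def classify_pausing(pi: float, category: PausingCategory = PausingCategory()) -> str:
    """'high' / 'moderate' / 'low' pausing label for one PI value."""
    if pi < 0:
        raise ValueError("PI cannot be negative")
    if pi >= category.high_min:
        return "high"
    if category.low_inclusive:
        return "low" if pi <= category.low_max else "moderate"
    return "moderate" if pi >= category.low_max else "low"


def condition_mean_pi(
    table: pd.DataFrame, sample_conditions: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean of replicate PIs per condition (columns = conditions)."""
    cols = pi_columns(table)
    by_cond: dict[str, list[str]] = {}
    for c in cols:
        sample = c[len("PI_"):]
        cond = sample_conditions[sample]
        by_cond.setdefault(cond, []).append(c)
    return pd.DataFrame(
        {cond: table[cs].mean(axis=1) for cond, cs in by_cond.items()}, index=table.index
    )


def pi_fold_change(
    table: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    contrast: tuple[str, str],
) -> pd.Series:
    """Per-gene log2(PI_b / PI_a) where per-condition PI is the replicate mean.

    ``contrast=(a, b)`` reports b relative to a (e.g. aged vs young).
    Genes with zero mean PI in either condition are excluded.
    """
    cond_a, cond_b = contrast
    means = condition_mean_pi(table, sample_conditions)
    for cond in contrast:
        if cond not in means.columns:
            raise ValueError(f"condition {cond!r} not present")
    valid = (means[cond_a] > 0) & (means[cond_b] > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("pi_fold_change: %d genes dropped (zero mean PI)", n_dropped)
    fc = np.log2(means.loc[valid, cond_b] / means.loc[valid, cond_a])
    fc.name = f"log2FC_PI_{cond_b}_vs_{cond_a}"
    return fc


def quantile_groups(values: pd.Series, k: int = 4) -> pd.Series:
    """Rank-based split into ``k`` near-equal groups (1 = lowest values).

    Ties broken by index label so the assignment is deterministic; the
    remainder genes go to the lowest groups, giving sizes differing by <= 1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = values.dropna()
    n = len(values)
    if n < k:
        raise ValueError(f"cannot split {n} values into {k} groups")
    order = values.to_frame("v").assign(_id=values.index.astype(str))
    order = order.sort_values(["v", "_id"]).index
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    labels = np.repeat(np.arange(1, k + 1), sizes)
    return pd.Series(labels, index=order, name="group").reindex(values.index)


def integrate_pi_accessibility(
    pi_fc: pd.Series, acc_fc: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join PI and promoter-accessibility fold changes; quadrant fractions.

    Returns (joined table, quadrant summary).  Quadrants are the four sign
    combinations of (accessibility change, PI change); genes with an exactly
    zero fold change in either axis are counted in the 'up' half (boundary
    convention, affects none of the simulated data).
    """
    joined = pd.DataFrame({"pi_log2fc": pi_fc, "acc_log2fc": acc_fc}).dropna()
    if joined.empty:
        raise ValueError("no shared genes between PI and accessibility tables")
    acc_up = joined["acc_log2fc"] >= 0
    pi_up = joined["pi_log2fc"] >= 0
    n = len(joined)
    quadrants = pd.DataFrame(
        [
            {"accessibility": a, "pausing": p,
             "n_genes": int(((acc_up == (a == "up")) & (pi_up == (p == "up"))).sum())}
            for a in ("up", "down")
            for p in ("up", "down")
        ]
    )
    quadrants["fraction"] = quadrants["n_genes"] / n
    return joined, quadrants
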