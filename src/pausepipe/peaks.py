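"""Consensus peak sets, active-enhancer identification and region annotation.

Replicate peak calls are merged into a consensus: the union of all peaks is
flattened into maximal non-overlapping regions, and a region is kept when at
least ``min_support`` distinct samples contribute >= 1 bp of overlap.  Active
enhancers are H3K27ac consensus regions that (i) do not overlap any H3K4me3
consensus region, (ii) do not fall within TSS +/- 1 kb of any gene, and
(iii) overlap at least one accessible (ATAC consensus) region.  Each
enhancer carries the per-rule outcome in its rule trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .density import DensityTrack, region_mean_density
from .regions import GeneModel, GenomicInterval, promoter_window


@dataclass
class PeakSet:
    """Peak calls from one sample."""

    peaks: list[GenomicInterval]
    sample_id: str
    scores: list[float] = field(default_factory=list)


@dataclass
class ConsensusPeakSet:
    regions: list[GenomicInterval]
    support: list[int]
    min_support: int

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class EnhancerSet:
    enhancers: list[GenomicInterval]
    rule_trail: pd.DataFrame  # per candidate: the three rule outcomes

    def __len__(self) -> int:
        return len(self.enhancers)


def _trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _any_overlap(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Flatten intervals into maximal non-overlapping regions (strand '.')."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # touching intervals merge
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, "."))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e, "."))
    return merged


def consensus_peaks(peak_sets: Sequence[PeakSet], min_support: int) -> ConsensusPeakSet:
    """Merged union of all peaks, restricted to regions supported by at
    least ``min_support`` distinct samples (>= 1 bp overlap each)."""
    if min_support > len(peak_sets):
        raise ValueError(
            f"min_support {min_support} exceeds number of peak sets {len(peak_sets)}"
        )
    union = merge_intervals([p for ps in peak_sets for p in ps.peaks])
    sample_trees = [_trees(ps.peaks) for ps in peak_sets]
    regions, support = [], []
    for region in union:
        n = sum(_any_overlap(trees, region) for trees in sample_trees)
        if n >= min_support:
            regions.append(region)
            support.append(n)
    return ConsensusPeakSet(regions=regions, support=support, min_support=min_support)


def subtract_blacklist(
    consensus: ConsensusPeakSet, blacklist: Sequence[GenomicInterval]
) -> ConsensusPeakSet:
    """Drop consensus regions with any overlap with a blacklist interval."""
    trees = _trees(blacklist)
    kept = [
        (r, s)
        for r, s in zip(consensus.regions, consensus.support)
        if not _any_overlap(trees, r)
    ]
    return ConsensusPeakSet(
        regions=[r for r, _ in kept],
        support=[s for _, s in kept],
        min_support=consensus.min_support,
    )


def identify_enhancers(
    k27ac: ConsensusPeakSet,
    k4me3: ConsensusPeakSet,
    atac: ConsensusPeakSet,
    genes: Sequence[GeneModel],
    tss_exclusion: int = 1000,
) -> EnhancerSet:
    """Active enhancers from H3K27ac consensus peaks by three conjunctive rules.

    A candidate passes when it has zero overlap with H3K4me3 regions, zero
    overlap with any TSS +/- ``tss_exclusion`` window, and >= 1 bp overlap
    with an ATAC consensus region.
    """
    k4_trees = _trees(k4me3.regions)
    atac_trees = _trees(atac.regions)
    tss_windows = [promoter_window(g, half_width=tss_exclusion) for g in genes]
    tss_trees = _trees(tss_windows)

    records = []
    enhancers = []
    for cand in k27ac.regions:
        no_k4 = not _any_overlap(k4_trees, cand)
        outside_tss = not _any_overlap(tss_trees, cand)
        has_atac = _any_overlap(atac_trees, cand)
        passed = no_k4 and outside_tss and has_atac
        records.append(
            {
                "chrom": cand.chrom,
                "start": cand.start,
                "end": cand.end,
                "no_k4me3_overlap": no_k4,
                "outside_tss_window": outside_tss,
                "atac_overlap": has_atac,
                "is_enhancer": passed,
            }
        )
        if passed:
            enhancers.append(cand)
    trail = pd.DataFrame.from_records(records)
    return EnhancerSet(enhancers=enhancers, rule_trail=trail)


FEATURE_PRECEDENCE = ("promoter", "five_prime_utr", "exon", "intron", "distal_intergenic")


def annotate_regions(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_half_width: int = 200,
    precedence: Sequence[str] = FEATURE_PRECEDENCE,
) -> list[str]:
    """Label each region by the genomic feature containing its midpoint.

    Features checked in ``precedence`` order: promoter (TSS +/- half width),
    5' UTR (between ORF start and first exon boundary upstream of the CDS is
    not modelled here — the 5' UTR is taken as the exonic sequence upstream
    of the ORF start within the gene's first exon), exon, intron, else
    distal intergenic.
    """
    prom_trees = _trees([promoter_window(g, half_width=promoter_half_width) for g in genes])

    utr, exons, spans = [], [], []
    for g in genes:
        for e in g.exons:
            exons.append(e)
            # exonic sequence 5' of the ORF start = annotated 5' UTR proxy
            if g.strand == "+" and e.start < g.tss:
                utr.append(GenomicInterval(g.chrom, e.start, min(e.end, g.tss + 1), "+"))
            elif g.strand == "-" and e.end > g.tss + 1:
                utr.append(GenomicInterval(g.chrom, max(e.start, g.tss), e.end, "-"))
        spans.append(g.span)
    feature_trees = {
        "promoter": prom_trees,
        "five_prime_utr": _trees(utr),
        "exon": _trees(exons),
        "intron": _trees(spans),  # in span but not exon => intron (checked below)
    }
    exon_trees = feature_trees["exon"]

    labels = []
    for region in regions:
        mid = int(region.midpoint)
        point = GenomicInterval(region.chrom, mid, mid + 1, ".")
        label = "distal_intergenic"
        for feat in precedence:
            if feat == "distal_intergenic":
                break
            if feat == "intron":
                hit = _any_overlap(feature_trees["intron"], point) and not _any_overlap(
                    exon_trees, point
                )
            else:
                hit = _any_overlap(feature_trees[feat], point)
            if hit:
                label = feat
                break
        labels.append(label)
    return labels


def overlap_fraction(
    query: Sequence[GenomicInterval], target: Sequence[GenomicInterval]
) -> tuple[int, float]:
    """(count, fraction) of query regions with >= 1 bp overlap with any target."""
    if not query:
        raise ValueError("overlap fraction undefined for an empty query set")
    trees = _trees(target)
    count = sum(_any_overlap(trees, q) for q in query)
    return count, count / len(query)


def erna_level(track: DensityTrack, enhancers: EnhancerSet) -> pd.Series:
    """Mean Pol II density per enhancer (both strands) as an eRNA proxy."""
    values = {
        f"{e.chrom}:{e.start}-{e.end}": region_mean_density(track, e, "both")
        for e in enhancers.enhancers
    }
    return pd.Series(values, name="erna_mean_density")


# ---------------------------------------------------------------------------
# narrowPeak / BED I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str, sample_id: str) -> PeakSet:
    """Read a narrowPeak (or BED3+) file into a PeakSet."""
    peaks, scores = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            peaks.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), "."))
            scores.append(float(fields[4]) if len(fields) > 4 else 0.0)
    return PeakSet(peaks=peaks, sample_id=sample_id, scores=scores)


def write_consensus_bed(consensus: ConsensusPeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for region, support in zip(consensus.regions, consensus.support):
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\tsupport={support}\n")


def write_enhancer_bed(enhancer_set: EnhancerSet, path: str) -> None:
    with open(path, "w") as fh:
        for e in enhancer_set.enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\tenhancer\n")
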