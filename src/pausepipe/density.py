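"""Per-base, per-strand signal tracks from alignment records.

NET-seq read 5' ends mark the 3' end of the nascent RNA and hence the exact
genomic position of engaged RNA polymerase II; ATAC-seq read 5' ends mark
transposase insertion points.  Both are recorded here at single-base
resolution into a sparse :class:`DensityTrack`, with the normalizations used
downstream:

* raw counts (integers);
* RPM — reads per million primary aligned reads (pausing index input);
* RPGC — reads per genomic content, scaling the genome-wide mean per-base
  signal to 1x (metagene input);
* RPKM for the gene coverage filter.

Tracks are keyed by (chromosome, strand); unstranded data uses strand '.'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .regions import GenomicInterval

logger = logging.getLogger(__name__)

Position = tuple[str, int, str]  # (chrom, 0-based position, strand)


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal mapped-read record (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    is_primary: bool = True
    is_mapped: bool = True
    is_supplementary: bool = False
    is_proper_pair: bool = True


@dataclass(frozen=True)
class LibrarySize:
    n_primary_aligned: int

    def __post_init__(self):
        if self.n_primary_aligned < 0:
            raise ValueError("library size cannot be negative")

    def __int__(self) -> int:
        return self.n_primary_aligned


@dataclass
class DensityTrack:
    """Sparse per-base signal: (chrom, strand) -> sorted positions + values.

    ``scale == 1.0`` means raw integer counts; RPM/RPGC tracks carry the
    applied multiplier in ``scale`` and keep the original ``library_size``.
    """

    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    scale: float = 1.0
    library_size: int = 0
    stranded: bool = True

    def total(self) -> float:
        return float(sum(v.sum() for _, v in self.data.values()))

    def strands_present(self) -> set[str]:
        return {s for (_c, s) in self.data}

    def _region_values(self, region: GenomicInterval, strand: str) -> np.ndarray:
        key = (region.chrom, strand)
        if key not in self.data:
            return np.empty(0)
        pos, val = self.data[key]
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        return val[lo:hi]

    def region_sum(self, region: GenomicInterval, strand: str = ".") -> float:
        """Total signal in [start, end) on one strand ('.' sums both)."""
        if strand == ".":
            strands = [s for s in ("+", "-", ".") if any(k[1] == s for k in self.data)]
            return float(sum(self._region_values(region, s).sum() for s in strands))
        return float(self._region_values(region, strand).sum())

    def region_window(self, chrom: str, start: int, end: int, strand: str = ".") -> np.ndarray:
        """Dense per-base array of length end-start for one strand ('.' = all)."""
        out = np.zeros(end - start)
        strands = [strand] if strand != "." else ["+", "-", "."]
        for s in strands:
            key = (chrom, s)
            if key not in self.data:
                continue
            pos, val = self.data[key]
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            out[pos[lo:hi] - start] += val[lo:hi]
        return out

    def scaled(self, factor: float) -> "DensityTrack":
        data = {k: (p.copy(), v * factor) for k, (p, v) in self.data.items()}
        return DensityTrack(
            data=data,
            scale=self.scale * factor,
            library_size=self.library_size,
            stranded=self.stranded,
        )


# ---------------------------------------------------------------------------
# Alignment streams
# ---------------------------------------------------------------------------

def count_primary_aligned(alignments: Iterable[AlignmentRecord]) -> LibrarySize:
    """Count mapped, primary, non-supplementary records (samtools -F 260
    semantics, with supplementary records additionally excluded)."""
    n = sum(
        1
        for a in alignments
        if a.is_mapped and a.is_primary and not a.is_supplementary
    )
    return LibrarySize(n)


def filter_alignments(
    alignments: Iterable[AlignmentRecord], min_mapq: int = 10
) -> Iterator[AlignmentRecord]:
    """Mapped, primary, non-supplementary records with MAPQ > ``min_mapq``."""
    for a in alignments:
        if a.is_mapped and a.is_primary and not a.is_supplementary and a.mapq > min_mapq:
            yield a


def five_prime_positions(alignments: Iterable[AlignmentRecord]) -> Iterator[Position]:
    """Strand-aware 5' end of each read.

    Plus-strand reads report ``start``; minus-strand reads report ``end - 1``
    (the genomically rightmost base).  Input is assumed pre-filtered.
    """
    for a in alignments:
        if a.strand == "+":
            yield (a.chrom, a.start, "+")
        else:
            yield (a.chrom, a.end - 1, "-")


def atac_cut_sites(alignments: Iterable[AlignmentRecord]) -> Iterator[Position]:
    """Strand-aware 5' end of every properly paired read, strand collapsed
    to '.'; no Tn5 offset applied."""
    for a in alignments:
        if not a.is_proper_pair:
            logger.warning("unpaired record at %s:%d skipped", a.chrom, a.start)
            continue
        pos = a.start if a.strand == "+" else a.end - 1
        yield (a.chrom, pos, ".")


def build_density(
    positions: Iterable[Position],
    library_size: LibrarySize | int,
    mode: str = "raw",
) -> DensityTrack:
    """Aggregate a position stream into a track.

    mode='raw' stores integer per-base counts; mode='RPM' multiplies by
    1e6 / library_size.
    """
    lib = int(library_size)
    if mode not in ("raw", "RPM"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "RPM" and lib <= 0:
        raise ValueError("RPM scaling requires a positive library size")

    buckets: dict[tuple[str, str], list[int]] = {}
    for chrom, pos, strand in positions:
        buckets.setdefault((chrom, strand), []).append(pos)

    data = {}
    stranded = True
    for key, plist in buckets.items():
        pos_arr, counts = np.unique(np.asarray(plist, dtype=np.int64), return_counts=True)
        data[key] = (pos_arr, counts.astype(float))
        if key[1] == ".":
            stranded = False

    track = DensityTrack(data=data, scale=1.0, library_size=lib, stranded=stranded)
    if mode == "RPM":
        track = track.scaled(1e6 / lib)
    return track


# ---------------------------------------------------------------------------
# Region statistics and normalizations
# ---------------------------------------------------------------------------

def region_mean_density(
    track: DensityTrack, region: GenomicInterval, strand_mode: str = "both"
) -> float:
    """Mean per-base signal over a region.

    strand_mode 'sense' uses the strand matching the region's own strand,
    'antisense' the opposite, 'both' sums all strands.  Bases without signal
    contribute zero.
    """
    if strand_mode not in ("sense", "antisense", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if strand_mode == "both":
        total = track.region_sum(region, ".")
    else:
        if region.strand == ".":
            raise ValueError("sense/antisense undefined for an unstranded region")
        flip = {"+": "-", "-": "+"}
        strand = region.strand if strand_mode == "sense" else flip[region.strand]
        total = track.region_sum(region, strand)
    return total / len(region)


def rpkm(count: float, region_length: int, library_size: LibrarySize | int) -> float:
    """Reads per kilobase per million mapped reads."""
    lib = int(library_size)
    if region_length < 1 or lib <= 0:
        raise ValueError("RPKM needs region_length >= 1 and library_size > 0")
    return count * 1e9 / (region_length * lib)


def rpgc_normalize(track: DensityTrack, effective_genome_size: int) -> DensityTrack:
    """Scale so genome-wide mean per-base signal is 1 (1x coverage)."""
    if effective_genome_size <= 0:
        raise ValueError("effective genome size must be positive")
    total = track.total()
    if total == 0:
        raise ValueError("cannot RPGC-normalize an empty track")
    return track.scaled(effective_genome_size / total)


# ---------------------------------------------------------------------------
# I/O: BAM / BED alignment dialect / bedGraph
# ---------------------------------------------------------------------------

def read_alignments_bam(path: str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a BAM/SAM file (requires pysam)."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped:
                continue
            yield AlignmentRecord(
                chrom=read.reference_name,
                start=read.reference_start,
                end=read.reference_end,
                strand="-" if read.is_reverse else "+",
                mapq=read.mapping_quality,
                is_primary=not read.is_secondary,
                is_mapped=True,
                is_supplementary=read.is_supplementary,
                is_proper_pair=read.is_proper_pair or not read.is_paired,
            )


def write_alignments_bam(
    records: Iterable[AlignmentRecord], chrom_lengths: dict[str, int], path: str
) -> None:
    """Write records as BAM (unsorted); requires pysam."""
    import pysam

    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    ref_id = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, r in enumerate(records):
            a = pysam.AlignedSegment()
            a.query_name = f"read_{i}"
            a.query_sequence = "N" * (r.end - r.start)
            a.reference_id = ref_id[r.chrom]
            a.reference_start = r.start
            a.cigar = [(0, r.end - r.start)]
            a.mapping_quality = r.mapq
            a.is_reverse = r.strand == "-"
            a.is_secondary = not r.is_primary
            a.is_supplementary = r.is_supplementary
            bam.write(a)


def read_alignments_bed(path: str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from the 6-column BED alignment dialect
    (chrom, start, end, name, mapq, strand)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, _name, mapq, strand = line.split()[:6]
            yield AlignmentRecord(
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                mapq=int(mapq),
            )


def write_bedgraph(track: DensityTrack, path_prefix: str) -> list[str]:
    """Write one 4-column bedGraph per strand present; returns paths written."""
    suffix = {"+": "plus", "-": "minus", ".": "unstranded"}
    by_strand: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {}
    for (chrom, strand), (pos, val) in sorted(track.data.items()):
        by_strand.setdefault(strand, []).append((chrom, pos, val))
    paths = []
    for strand, entries in sorted(by_strand.items()):
        path = f"{path_prefix}.{suffix[strand]}.bedgraph"
        with open(path, "w") as fh:
            for chrom, pos, val in entries:
                for p, v in zip(pos, val):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:g}\n")
        paths.append(path)
    return paths


def read_bedgraph_pair(
    plus_path: str | None = None,
    minus_path: str | None = None,
    unstranded_path: str | None = None,
    library_size: int = 0,
    scale: float = 1.0,
) -> DensityTrack:
    """Load per-strand single-base bedGraph files back into a track."""
    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-"), (unstranded_path, ".")):
        if path is None:
            continue
        chroms: dict[str, list[tuple[int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, value = line.split()[:4]
                start_i, end_i = int(start), int(end)
                for p in range(start_i, end_i):
                    chroms.setdefault(chrom, []).append((p, float(value)))
        for chrom, pairs in chroms.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            val = np.array([v for _, v in pairs])
            data[(chrom, strand)] = (pos, val)
    stranded = unstranded_path is None
    return DensityTrack(data=data, scale=scale, library_size=library_size, stranded=stranded)
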