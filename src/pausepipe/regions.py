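"""Gene annotation, analyzable-gene selection and strand-aware analysis windows.

The analyses downstream (pausing index, differential transcription) require a
conservative gene set: protein-coding genes long enough to separate the
promoter-proximal region from the gene body, and isolated enough that signal
cannot bleed over from neighbouring transcription units.  This module parses
an Ensembl-dialect GTF into :class:`GeneModel` objects anchored on the
canonical transcript's open reading frame, applies the structural filters,
and derives every window used later:

* promoter window — TSS +/- ``half_width`` bp (inclusive, 401 bp by default);
* gene body — TSS + ``trim`` to TES - ``trim`` in transcription direction;
* narrow pause window — TSS +20 to +100 bp, where engaged polymerase
  physically stalls.

All internal coordinates are 0-based half-open; GTF input is converted from
its native 1-based closed convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"GTF line {line_number}: {message}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval.  Strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """Gene anchored on its canonical transcript's ORF.

    ``tss``/``tes`` are the 5'/3' ends of the canonical ORF in transcription
    direction: for a minus-strand gene ``tss > tes`` in genomic coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)
    canonical_transcript_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")
        if self.strand == "+" and self.tss >= self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand needs tss < tes")
        if self.strand == "-" and self.tss <= self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand needs tss > tes")

    @property
    def span_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def span_end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.span_start, self.span_end, self.strand)


@dataclass
class GeneSet:
    """Retained genes plus a per-gene log of the first filter that removed it."""

    genes: list[GeneModel]
    selection_log: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


# ---------------------------------------------------------------------------
# GTF loading
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(
    path: str,
    biotype_filter: set[str] | None = None,
) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    The canonical transcript is the one with the longest total CDS length if
    the gene has any coding transcript, otherwise the longest total exon
    (cDNA) length; ties broken by lexicographically smallest transcript id.
    TSS/TES are the ORF ends of that transcript when it is coding, else the
    transcript ends.  Genes without any transcript are skipped and logged.

    Parameters
    ----------
    path:
        GTF file (1-based closed coordinates, attributes ``gene_id``,
        ``transcript_id``, ``gene_biotype``).
    biotype_filter:
        If given, keep only genes whose ``gene_biotype`` is in the set.
    """
    # per gene: biotype/chrom/strand; per transcript: exon + CDS intervals
    gene_meta: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(lineno, "non-integer coordinates") from None
            if start1 > end1:
                raise GTFParseError(lineno, f"start {start1} > end {end1}")
            if strand not in ("+", "-"):
                continue  # unstranded features are not genes
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GTFParseError(lineno, "missing gene_id attribute")
            start0 = start1 - 1  # to 0-based half-open
            if feature == "gene":
                gene_meta[gene_id] = {
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", ""),
                }
            elif feature == "transcript":
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GTFParseError(lineno, "transcript without transcript_id")
                tx_parent[tx_id] = gene_id
                tx_exons.setdefault(tx_id, [])
                tx_cds.setdefault(tx_id, [])
                gene_meta.setdefault(
                    gene_id,
                    {"chrom": chrom, "strand": strand, "biotype": attrs.get("gene_biotype", "")},
                )
            elif feature in ("exon", "CDS"):
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GTFParseError(lineno, f"{feature} without transcript_id")
                tx_parent.setdefault(tx_id, gene_id)
                target = tx_exons if feature == "exon" else tx_cds
                target.setdefault(tx_id, []).append((start0, end1))

    # group transcripts by gene
    gene_tx: dict[str, list[str]] = {}
    for tx_id, gid in tx_parent.items():
        gene_tx.setdefault(gid, []).append(tx_id)

    genes: list[GeneModel] = []
    for gene_id, meta in gene_meta.items():
        if biotype_filter is not None and meta["biotype"] not in biotype_filter:
            continue
        tx_ids = gene_tx.get(gene_id, [])
        if not tx_ids:
            logger.warning("gene %s has no transcripts; skipped", gene_id)
            continue
        cds_len = {t: sum(e - s for s, e in tx_cds.get(t, [])) for t in tx_ids}
        exon_len = {t: sum(e - s for s, e in tx_exons.get(t, [])) for t in tx_ids}
        coding = [t for t in tx_ids if cds_len[t] > 0]
        if coding:
            canonical = min(coding, key=lambda t: (-cds_len[t], t))
            blocks = sorted(tx_cds[canonical])
        else:
            canonical = min(tx_ids, key=lambda t: (-exon_len[t], t))
            blocks = sorted(tx_exons[canonical])
        if not blocks:
            logger.warning("gene %s canonical transcript has no blocks; skipped", gene_id)
            continue
        left, right = blocks[0][0], blocks[-1][1]
        strand = meta["strand"]
        tss, tes = (left, right) if strand == "+" else (right, left)
        exons = [
            GenomicInterval(meta["chrom"], s, e, strand)
            for s, e in sorted(tx_exons.get(canonical, blocks))
        ]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=meta["chrom"],
                strand=strand,
                tss=tss,
                tes=tes,
                biotype=meta["biotype"],
                exons=exons,
                canonical_transcript_id=canonical,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------------

def select_tnet_genes(
    genes: Sequence[GeneModel],
    min_length: int = 2000,
    isolation: int = 2500,
    biotype: str = "protein_coding",
) -> GeneSet:
    """Select the analyzable gene set: coding, long, and isolated.

    A gene is retained when (in order of testing):

    1. its biotype equals ``biotype``;
    2. its ORF span (tss..tes) is strictly longer than ``min_length``;
    3. its isolation envelope, the span extended by ``isolation`` bp on both
       sides, overlaps no other annotated gene's span (any biotype).

    ``selection_log`` records the first failing filter for every removed gene,
    so input genes partition exactly into retained + logged.
    """
    result_genes: list[GeneModel] = []
    log: dict[str, str] = {}

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.span_start, g.span_end, g.gene_id))

    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.biotype != biotype:
            log[g.gene_id] = "biotype"
            continue
        if g.span_length <= min_length:
            log[g.gene_id] = "length"
            continue
        env_start = g.span_start - isolation
        env_end = g.span_end + isolation
        crowded = False
        for other in by_chrom[g.chrom]:
            if other.gene_id == g.gene_id:
                continue
            if other.span_start < env_end and env_start < other.span_end:
                crowded = True
                break
        if crowded:
            log[g.gene_id] = "isolation"
            continue
        result_genes.append(g)

    result_genes.sort(key=lambda g: (g.chrom, g.span_start, g.gene_id))
    return GeneSet(genes=result_genes, selection_log=log)


def coverage_filter(gene_set: GeneSet, track, rpkm_min: float = 1.0) -> GeneSet:
    """Keep genes with sense-strand RPKM above ``rpkm_min`` over the ORF span.

    ``track`` is a raw-count :class:`~pausepipe.density.DensityTrack` whose
    ``library_size`` is used as the RPKM denominator.
    """
    from .density import rpkm  # local import to avoid cycle

    if track.library_size <= 0:
        raise ValueError("coverage filter needs a positive library size")
    kept: list[GeneModel] = []
    log = dict(gene_set.selection_log)
    for g in gene_set.genes:
        count = track.region_sum(g.span, strand=g.strand)
        value = rpkm(count, g.span_length, track.library_size)
        if value > rpkm_min:
            kept.append(g)
        else:
            log[g.gene_id] = "coverage"
    return GeneSet(genes=kept, selection_log=log)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneModel, half_width: int = 200) -> GenomicInterval:
    """TSS +/- ``half_width`` bp, inclusive of both endpoints (401 bp default).

    Symmetric in genomic coordinates regardless of strand; clipped at the
    chromosome start if necessary.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    start = gene.tss - half_width
    end = gene.tss + half_width + 1
    if start < 0:
        logger.warning("promoter window of %s clipped at chromosome start", gene.gene_id)
        start = 0
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def gene_body_region(gene: GeneModel, trim: int = 200) -> GenomicInterval:
    """Transcription-oriented body: TSS + ``trim`` to TES - ``trim``."""
    if gene.span_length <= 2 * trim:
        raise ValueError(
            f"gene {gene.gene_id} span {gene.span_length} too short for trim {trim}"
        )
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tss + trim, gene.tes - trim, "+")
    return GenomicInterval(gene.chrom, gene.tes + trim, gene.tss - trim, "-")


def narrow_pause_window(gene: GeneModel) -> GenomicInterval:
    """80-bp window TSS +20 to +100 in transcription direction."""
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tss + 20, gene.tss + 100, "+")
    return GenomicInterval(gene.chrom, gene.tss - 100, gene.tss - 20, "-")


def nearest_tss_distance(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> np.ndarray:
    """Distance from each region's midpoint to the closest TSS.

    Zero when a TSS lies inside the region.  TSSs on other chromosomes are
    ignored; a region on a chromosome with no gene gets ``inf``.
    """
    if not genes:
        raise ValueError("need at least one gene")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v, dtype=float)) for c, v in tss_by_chrom.items()}

    out = np.full(len(regions), np.inf)
    for i, region in enumerate(regions):
        tss = tss_by_chrom.get(region.chrom)
        if tss is None:
            continue
        inside = (tss >= region.start) & (tss < region.end)
        if inside.any():
            out[i] = 0.0
            continue
        out[i] = np.abs(tss - region.midpoint).min()
    return out


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------

def write_bed6(intervals: Iterable[GenomicInterval], names: Iterable[str], path: str) -> None:
    """Write intervals as BED6 (name per interval, score 0)."""
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
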