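"""Coordinate types, BED/gene-table IO, and interval arithmetic.

All coordinates are 0-based half-open (BED convention) throughout the
package; readers of 1-based dialects convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

STRAND_UNSPECIFIED = "."


class BedParseError(ValueError):
    """Malformed BED-like input; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``+``, ``-``, or ``.`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNSPECIFIED
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", STRAND_UNSPECIFIED):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakRecord:
    """A called ChIP-seq peak: interval plus enrichment and significance.

    ``enrichment`` is the fold/score emitted by the peak caller;
    ``significance`` an FDR or p-value. ``library`` tags factor+species.
    """

    interval: GenomicInterval
    enrichment: float = 0.0
    significance: float = 0.0
    library: str = ""

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str:
        return self.interval.name

    def center(self) -> int:
        return self.interval.center()


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with mandatory strand; TSS derived from orientation."""

    gene_id: str
    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.symbol:
            raise ValueError(f"gene {self.gene_id}: symbol must be non-empty")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

#: default column map: BED5 with enrichment in the score column
DEFAULT_SCORE_COLUMNS: Mapping[str, int] = {"enrichment": 4}


def read_bed(
    path,
    score_columns: Mapping[str, int] | None = None,
    library: str = "",
) -> list[PeakRecord]:
    """Read a BED-like file into PeakRecords, preserving input order.

    ``score_columns`` maps field names (``enrichment``, ``significance``)
    to 0-based column indices; columns absent from a line default to 0.
    Raises :class:`BedParseError` naming the line number on malformed
    input.
    """
    cols = dict(DEFAULT_SCORE_COLUMNS if score_columns is None else score_columns)
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"line{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else STRAND_UNSPECIFIED
            try:
                iv = GenomicInterval(fields[0], start, end, strand=strand, name=name)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            scores = {}
            for key, idx in cols.items():
                if idx < len(fields) and fields[idx] != "":
                    scores[key] = float(fields[idx])
            records.append(
                PeakRecord(
                    iv,
                    enrichment=scores.get("enrichment", 0.0),
                    significance=scores.get("significance", 0.0),
                    library=library,
                )
            )
    return records


def write_bed(path, records: Iterable[PeakRecord], score_columns: Mapping[str, int] | None = None) -> None:
    """Write PeakRecords as tab-separated, LF-terminated BED lines.

    Inverse of :func:`read_bed` under the same column map.
    """
    cols = dict(DEFAULT_SCORE_COLUMNS if score_columns is None else score_columns)
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            n_fields = max([6] + [i + 1 for i in cols.values()])
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, "0", iv.strand]
            fields += ["0"] * (n_fields - len(fields))
            for key, idx in cols.items():
                # shortest round-tripping float representation
                fields[idx] = repr(float(getattr(rec, key)))
            fh.write("\t".join(fields) + "\n")


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read a refGene-like TSV: name, chrom, strand, txStart, txEnd[, name2].

    txStart/txEnd are taken as 0-based half-open (the UCSC database
    convention for this table).
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"{path}:{lineno}: fewer than 5 columns")
            name, chrom, strand = fields[0], fields[1], fields[2]
            start, end = int(fields[3]), int(fields[4])
            symbol = fields[5] if len(fields) > 5 and fields[5] else name
            genes.append(
                GeneAnnotation(name, symbol, GenomicInterval(chrom, start, end, strand=strand, name=name))
            )
    return genes


def write_gene_table(path, genes: Iterable[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write("\t".join([g.gene_id, iv.chrom, iv.strand, str(iv.start), str(iv.end), g.symbol]) + "\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def standardize(peak: PeakRecord | GenomicInterval, width: int) -> GenomicInterval:
    """Re-center an interval on the peak center at a fixed width.

    The interval becomes [center - floor(width/2), same + width), clipped
    at 0 (the clipped interval is shorter). For odd widths the extra base
    falls rightward of the center.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    iv = peak.interval if isinstance(peak, PeakRecord) else peak
    start = iv.center() - width // 2
    end = start + width
    start = max(0, start)
    return GenomicInterval(iv.chrom, start, end, strand=iv.strand, name=iv.name)


def extend_tag(tag: GenomicInterval, extension: int) -> GenomicInterval:
    """Extend a sequenced tag to the ChIP fragment length.

    Stranded tags are extended in their 3' direction to ``extension`` bp
    total; unspecified-strand tags are extended symmetrically. Tags
    already at least ``extension`` bp wide are returned unchanged.
    """
    if extension <= tag.width:
        return tag
    if tag.strand == "+":
        start, end = tag.start, tag.start + extension
    elif tag.strand == "-":
        start, end = tag.end - extension, tag.end
    else:
        pad = extension - tag.width
        start = tag.start - pad // 2
        end = tag.end + (pad - pad // 2)
    return GenomicInterval(tag.chrom, max(0, start), end, strand=tag.strand, name=tag.name)


def coverage_counts(
    tags: Sequence[GenomicInterval],
    loci: Sequence[GenomicInterval],
    extension: int = 250,
) -> list[int]:
    """Per-locus tag counts after 3' extension of tags.

    A tag counts for a locus when its extended interval overlaps the
    locus by at least one base. Returns one count per locus, in order.
    """
    trees: dict[str, IntervalTree] = {}
    for locus_idx, locus in enumerate(loci):
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, locus_idx)
    counts = [0] * len(loci)
    for tag in tags:
        ext = extend_tag(tag, extension) if extension > 0 else tag
        tree = trees.get(ext.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(ext.start, ext.end):
            counts[hit.data] += 1
    return counts


def quartile_split(peaks: Sequence[PeakRecord]) -> list[list[PeakRecord]]:
    """Split peaks into four enrichment quartiles, strongest first.

    Peaks are stably sorted by enrichment descending (ties keep input
    order) and cut into four groups; remainders go to the strongest
    quartiles. The groups partition the input.
    """
    n = len(peaks)
    if n < 4:
        raise ValueError("quartile_split requires at least 4 peaks")
    ordered = sorted(peaks, key=lambda p: -p.enrichment)  # stable: ties keep input order
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    groups, pos = [], 0
    for size in sizes:
        groups.append(ordered[pos : pos + size])
        pos += size
    return groups
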