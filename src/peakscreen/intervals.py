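"""Genomic interval primitives.

All internal coordinates are 0-based, half-open (the convention of BED and
bedGraph).  Printed tables in the yeast literature use 1-based inclusive
coordinates; :func:`convert_coords` / :meth:`GenomeInterval.to_1based` convert
at the IO boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import CoordinateError, ConfigurationError

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A located span on a named chromosome.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``'+'``, ``'-'`` or
    ``'.'`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start {self.start}")
        if self.end <= self.start:
            raise CoordinateError(
                f"empty or inverted span {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """Return the printed-table (1-based inclusive) coordinates."""
        return self.start + 1, self.end

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def convert_coords(start_1based: int, end_1based: int, chrom: str = "",
                   strand: str = ".") -> GenomeInterval:
    """Convert 1-based inclusive printed coordinates to a half-open interval.

    ``(465396, 465409)`` maps to ``(465395, 465409)`` — width 14, the length
    of a printed 14-mer motif.
    """
    if start_1based < 1:
        raise CoordinateError(f"1-based start must be >= 1, got {start_1based}")
    if end_1based < start_1based:
        raise CoordinateError(
            f"inverted 1-based span ({start_1based}, {end_1based})"
        )
    return GenomeInterval(chrom, start_1based - 1, end_1based, strand)


def merge_intervals(intervals: Iterable[GenomeInterval],
                    max_gap: int = 0) -> list[GenomeInterval]:
    """Merge intervals whose gap is <= ``max_gap``, per chromosome.

    Output is sorted (chrom, start), unstranded, idempotent and invariant to
    input order.  A gap of exactly ``max_gap`` bases is merged; larger gaps
    separate regions.
    """
    if max_gap < 0:
        raise ConfigurationError(f"max_gap must be non-negative, got {max_gap}")
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomeInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= max_gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomeInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomeInterval(iv.chrom, iv.start, iv.end))
    return merged


def interval_overlap_length(a: GenomeInterval, b: GenomeInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene annotation: id, genomic span, and the exonic length used for FPKM.

    For the single-span models used here ``length_bp`` defaults to the
    interval width.
    """

    gene_id: str
    interval: GenomeInterval
    length_bp: int = 0

    def __post_init__(self) -> None:
        if self.length_bp == 0:
            object.__setattr__(self, "length_bp", self.interval.width)
        if self.length_bp <= 0:
            raise CoordinateError(f"gene {self.gene_id}: length_bp must be > 0")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site (strand-aware)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    def promoter(self, window: int) -> GenomeInterval | None:
        """The ``window`` bases immediately upstream of the TSS, or None at a
        chromosome edge."""
        if window <= 0:
            raise ConfigurationError("promoter window must be > 0")
        if self.interval.strand == "-":
            return GenomeInterval(self.interval.chrom, self.interval.end,
                                  self.interval.end + window, "-")
        start = max(0, self.interval.start - window)
        if start == self.interval.start:
            return None
        return GenomeInterval(self.interval.chrom, start, self.interval.start, "+")
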