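"""Per-base coverage tracks and the bedGraph interface.

A :class:`CoverageTrack` holds dense per-base values for one or more
chromosomes plus the library total used for depth normalization.  Raw pileup
tracks are non-negative; ChIP-minus-input *difference* tracks are a derived,
signed variant (``signed=True``) and are defined at every base (uncovered
bases are 0).
"""
from __future__ import annotations

import io
import os
from typing import Mapping, TextIO, Union

import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, NormalizationError, ShapeError
from .intervals import GenomeInterval

PathOrHandle = Union[str, os.PathLike, TextIO]


class CoverageTrack:
    """Dense per-base signal keyed by chromosome.

    Parameters
    ----------
    values
        Mapping chromosome -> 1-D float array (one entry per base).
    library_total
        Total signal/fragment count of the library the track came from.
        Defaults to the sum of all values (only meaningful for raw pileups).
    signed
        Allow negative values (difference tracks).
    """

    def __init__(self, values: Mapping[str, np.ndarray],
                 library_total: float | None = None,
                 signed: bool = False) -> None:
        self.values: dict[str, np.ndarray] = {
            c: np.asarray(v, dtype=np.float64) for c, v in values.items()
        }
        for c, v in self.values.items():
            if v.ndim != 1:
                raise ShapeError(f"{c}: values must be 1-D")
            if not signed and v.size and float(v.min()) < 0:
                raise FormatError(f"{c}: negative values in an unsigned track")
        self.signed = signed
        if library_total is None:
            # difference tracks have no meaningful library of their own
            library_total = 0.0 if signed else float(
                sum(v.sum() for v in self.values.values()))
        if library_total < 0:
            raise NormalizationError("library_total must be >= 0")
        self.library_total = float(library_total)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: v.size for c, v in self.values.items()}

    def region(self, interval: GenomeInterval) -> np.ndarray:
        """Values over an interval (a view)."""
        if interval.chrom not in self.values:
            raise BoundsError(f"unknown chromosome {interval.chrom}")
        v = self.values[interval.chrom]
        if interval.end > v.size:
            raise BoundsError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {v.size}"
            )
        return v[interval.start:interval.end]

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: v * factor for c, v in self.values.items()},
            library_total=self.library_total * factor,
            signed=self.signed,
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack({c: v.copy() for c, v in self.values.items()},
                             library_total=self.library_total,
                             signed=self.signed)

    def allclose(self, other: "CoverageTrack", **kw) -> bool:
        return set(self.values) == set(other.values) and all(
            np.allclose(self.values[c], other.values[c], **kw)
            for c in self.values
        )


def read_bedgraph(source: PathOrHandle,
                  chrom_lengths: Mapping[str, int],
                  library_total: float | None = None,
                  signed: bool = False) -> CoverageTrack:
    """Expand a 4-column bedGraph into a per-base :class:`CoverageTrack`.

    Records may arrive unsorted; overlapping records or records beyond the
    declared chromosome end raise :class:`FormatError`.  Bases covered by no
    record are 0.
    """
    df = pd.read_csv(source, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    values = {c: np.zeros(int(n), dtype=np.float64)
              for c, n in chrom_lengths.items()}
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    prev_end: dict[str, int] = {}
    for chrom, start, end, value in df.itertuples(index=False):
        start, end = int(start), int(end)
        if chrom not in values:
            raise FormatError(f"record on undeclared chromosome {chrom}")
        if start < 0 or end <= start:
            raise FormatError(f"bad bedGraph span {chrom}:{start}-{end}")
        if end > values[chrom].size:
            raise FormatError(
                f"record {chrom}:{start}-{end} beyond chromosome end "
                f"{values[chrom].size}"
            )
        if start < prev_end.get(chrom, 0):
            raise FormatError(f"overlapping bedGraph records at {chrom}:{start}")
        prev_end[chrom] = end
        values[chrom][start:end] = float(value)
    return CoverageTrack(values, library_total=library_total, signed=signed)


def write_bedgraph(track: CoverageTrack, dest: PathOrHandle) -> None:
    """Write a track as run-length-encoded bedGraph; zero runs are omitted.

    ``repr`` float formatting makes write-then-read round trips bit-exact.
    """
    own = isinstance(dest, (str, os.PathLike))
    handle = open(dest, "w") if own else dest
    try:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if v.size == 0:
                continue
            breaks = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [v.size]))
            for s, e in zip(starts, ends):
                x = float(v[s])
                if x == 0.0:
                    continue
                handle.write(f"{chrom}\t{s}\t{e}\t{x!r}\n")
    finally:
        if own:
            handle.close()


def normalize_pair(chip: CoverageTrack,
                   input_: CoverageTrack) -> tuple[CoverageTrack, CoverageTrack]:
    """Depth-normalize a ChIP/input pair by scaling the deeper library down.

    The track with the larger library total is multiplied by
    ``min(totals)/own_total``; the shallower track is returned unchanged, so
    the normalized totals are equal.
    """
    if chip.library_total <= 0 or input_.library_total <= 0:
        raise NormalizationError("both library totals must be > 0")
    target = min(chip.library_total, input_.library_total)
    chip_n = chip if chip.library_total == target else chip.scaled(target / chip.library_total)
    input_n = input_ if input_.library_total == target else input_.scaled(target / input_.library_total)
    return chip_n, input_n


def diff_track(chip_norm: CoverageTrack,
               input_norm: CoverageTrack) -> CoverageTrack:
    """Per-base ChIP-minus-input difference track (signed)."""
    if chip_norm.chrom_lengths != input_norm.chrom_lengths:
        raise ShapeError(
            f"chromosome sets/lengths differ: {chip_norm.chrom_lengths} vs "
            f"{input_norm.chrom_lengths}"
        )
    return CoverageTrack(
        {c: chip_norm.values[c] - input_norm.values[c] for c in chip_norm.values},
        library_total=0.0,
        signed=True,
    )
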