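"""Peak-call consolidation and peak shape metrics.

ChIP peak callers disagree on boundaries; calls from all callers, replicates
and conditions are merged into *consolidated regions* which carry the
cross-caller/cross-replicate support bookkeeping the confidence screen needs.
Shape metrics are computed on the normalized ChIP-minus-input difference
track:

* ``summit_height`` — maximum of the difference over the region; the summit
  position takes the leftmost maximizer on ties.
* ``pileup_log2fc`` — log2 of (mean ChIP / mean input) over the region, with
  a pseudocount for bounded output on empty input.
* ``width_at_half_max`` — bases with signal >= half the summit height.
* ``area`` — sum of positive differences.
* ``symmetry_ratio`` — min/max of the positive area strictly left/right of
  the summit (1 for a perfectly symmetric peak).

Regions where the difference never rises above zero are flagged degenerate.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .errors import BoundsError, ConfigurationError, FormatError
from .intervals import GenomeInterval, interval_overlap_length, merge_intervals

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signalValue", "pValue", "qValue", "peak"]


@dataclass(frozen=True)
class PeakCall:
    """One caller's peak call for one replicate of one condition."""

    interval: GenomeInterval
    caller_id: str
    replicate_id: str
    condition_id: str
    caller_score: float = 0.0


@dataclass(frozen=True)
class PeakShapeMetrics:
    summit_offset: int
    summit_height: float
    pileup_log2fc: float
    width_at_half_max: int
    area: float
    symmetry_ratio: float
    degenerate: bool = False


@dataclass
class ConsolidatedRegion:
    """Merged span of overlapping peak calls, with support and metrics."""

    region_id: str
    interval: GenomeInterval
    caller_support: frozenset[str]
    replicate_support: dict[str, int]
    metrics: dict[str, PeakShapeMetrics] = field(default_factory=dict)
    negative_flag: bool = False
    hyperchip_flag: bool = False


def region_summit_and_shape(region: GenomeInterval,
                            diff: CoverageTrack) -> PeakShapeMetrics:
    """Summit, width, area and symmetry of a region on a difference track.

    ``pileup_log2fc`` is filled separately (it needs the normalized ChIP and
    input tracks, not the difference) and is NaN here.
    """
    d = diff.region(region)
    summit_offset = int(np.argmax(d))  # leftmost maximizer
    summit_height = float(d[summit_offset])
    pos = np.maximum(d, 0.0)
    area = float(pos.sum())
    if summit_height <= 0:
        return PeakShapeMetrics(summit_offset, summit_height, math.nan,
                                0, area, 1.0, degenerate=True)
    width = int(np.count_nonzero(d >= summit_height / 2.0))
    left = float(pos[:summit_offset].sum())
    right = float(pos[summit_offset + 1:].sum())
    if left == 0.0 and right == 0.0:
        symmetry = 1.0
    else:
        symmetry = min(left, right) / max(left, right)
    return PeakShapeMetrics(summit_offset, summit_height, math.nan,
                            width, area, symmetry)


def region_pileup_log2fc(region: GenomeInterval,
                         chip_norm: CoverageTrack,
                         input_norm: CoverageTrack,
                         pseudocount: float = 1.0) -> float:
    """log2((mean ChIP + pc) / (mean input + pc)) over a region."""
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    c = chip_norm.region(region)
    i = input_norm.region(region)
    if c.size == 0:
        raise BoundsError("empty region")
    return float(np.log2((c.mean() + pseudocount) / (i.mean() + pseudocount)))


def consolidate_peaks(calls: Sequence[PeakCall],
                      max_gap: int = 0) -> list[ConsolidatedRegion]:
    """Merge peak calls from all callers/replicates into consolidated regions.

    Each region records the distinct callers supporting it and, per
    condition, the number of distinct replicates contributing at least one
    overlapping call.  Region ids are assigned by genomic order.
    """
    if not calls:
        return []
    spans = merge_intervals([c.interval for c in calls], max_gap=max_gap)
    regions = []
    for k, span in enumerate(spans, start=1):
        overlapping = [c for c in calls
                       if interval_overlap_length(c.interval, span) > 0]
        callers = frozenset(c.caller_id for c in overlapping)
        support: dict[str, int] = {}
        for cond in sorted({c.condition_id for c in overlapping}):
            reps = {c.replicate_id for c in overlapping if c.condition_id == cond}
            support[cond] = len(reps)
        regions.append(ConsolidatedRegion(str(k), span, callers, support))
    return regions


def detect_negative_regions(diff: CoverageTrack,
                            depth_threshold: float,
                            min_width: int) -> list[GenomeInterval]:
    """Maximal runs where the difference is <= -depth_threshold, of length
    >= min_width — the 'negative peak' signature of input over ChIP."""
    if depth_threshold <= 0 or min_width <= 0:
        raise ConfigurationError("depth_threshold and min_width must be > 0")
    out = []
    for chrom in sorted(diff.values):
        v = diff.values[chrom]
        mask = v <= -depth_threshold
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False])).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_width:
                out.append(GenomeInterval(chrom, int(s), int(e)))
    return out


def replicate_consensus_metrics(
    per_replicate: Sequence[PeakShapeMetrics],
    n_replicates: int,
) -> tuple[PeakShapeMetrics | None, int]:
    """Arithmetic mean of each metric over contributing replicates.

    Returns ``(None, 0)`` for an empty list (explicit absent marker).
    """
    support = len(per_replicate)
    if support == 0:
        return None, 0
    if support > n_replicates:
        raise ConfigurationError(
            f"{support} replicate metrics but only {n_replicates} replicates"
        )

    def mean(attr: str) -> float:
        vals = [getattr(m, attr) for m in per_replicate]
        return float(np.mean(vals))

    return PeakShapeMetrics(
        summit_offset=int(round(mean("summit_offset"))),
        summit_height=mean("summit_height"),
        pileup_log2fc=mean("pileup_log2fc"),
        width_at_half_max=int(round(mean("width_at_half_max"))),
        area=mean("area"),
        symmetry_ratio=mean("symmetry_ratio"),
        degenerate=any(m.degenerate for m in per_replicate),
    ), support


def read_narrowpeak(path: str | os.PathLike, caller_id: str,
                    replicate_id: str, condition_id: str) -> list[PeakCall]:
    """Read caller output in narrowPeak (BED6+4) or plain BED format."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 tab-separated columns")
    calls = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] > 5 and row[5] in "+-" else "."
        score = float(row[6]) if df.shape[1] >= 7 else (
            float(row[4]) if df.shape[1] > 4 and row[4] != "." else 0.0)
        iv = GenomeInterval(str(row[0]), int(row[1]), int(row[2]), strand)
        calls.append(PeakCall(iv, caller_id, replicate_id, condition_id, score))
    return calls


def write_narrowpeak(calls: Iterable[PeakCall], path: str | os.PathLike) -> None:
    rows = []
    for c in calls:
        name = f"{c.caller_id}.{c.condition_id}.{c.replicate_id}"
        rows.append((c.interval.chrom, c.interval.start, c.interval.end, name,
                     0, ".", c.caller_score, -1, -1, -1))
    pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False)


def write_regions_bed(regions: Iterable[ConsolidatedRegion],
                      path: str | os.PathLike) -> None:
    """Consolidated regions as BED6 with the region id in the name field."""
    rows = [(r.interval.chrom, r.interval.start, r.interval.end, r.region_id,
             len(r.caller_support), ".") for r in regions]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def metrics_table(regions: Iterable[ConsolidatedRegion]) -> pd.DataFrame:
    """Long-format metrics table keyed by (region_id, condition_id)."""
    rows = []
    for r in regions:
        for cond, m in sorted(r.metrics.items()):
            rows.append({
                "region_id": r.region_id,
                "condition_id": cond,
                "summit_pos": r.interval.start + m.summit_offset,
                "summit_height": m.summit_height,
                "pileup_log2fc": m.pileup_log2fc,
                "width_at_half_max": m.width_at_half_max,
                "area": m.area,
                "symmetry_ratio": m.symmetry_ratio,
                "degenerate": int(m.degenerate),
                "replicate_support": r.replicate_support.get(cond, 0),
            })
    return pd.DataFrame(rows)
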