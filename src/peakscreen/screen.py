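"""Confidence screening of consolidated ChIP peak regions.

Two artifact classes motivate the screen:

* *Hyper-ChIPable* loci — highly expressed gene bodies that show apparent
  ChIP enrichment regardless of true binding.  A region whose span lies
  mostly inside a gene body whose expression percentile (against all loci,
  in the region's own conditions) reaches the configured cutoff is flagged.
* *Negative peaks* — input-over-ChIP enrichment; any consolidated region
  overlapping a detected negative region is flagged.

Regions are then tiered: ``high`` requires support from every caller,
replicate support and shape metrics above thresholds in at least one
condition, and neither artifact flag; either artifact flag (or no signal at
all) gives ``rejected``; everything else is ``ambiguous``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError
from .intervals import GeneModel, GenomeInterval, interval_overlap_length
from .peaks import ConsolidatedRegion

GENE_BODY = "gene_body"
PROMOTER = "promoter"
INTERGENIC = "intergenic"

TIER_HIGH = "high"
TIER_AMBIGUOUS = "ambiguous"
TIER_REJECTED = "rejected"


@dataclass(frozen=True)
class PeakContext:
    """Where a consolidated region sits relative to the gene annotation."""

    region_id: str
    context_label: str
    overlapped_gene: str | None
    gene_body_overlap_fraction: float


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the confidence screen (all configurable).

    ``hyperchip_percentile`` — expression percentile (vs all loci) at or
    above which a gene-body region is considered hyper-ChIPable.
    ``min_summit`` is in normalized ChIP-minus-input units.
    """

    hyperchip_percentile: float = 90.0
    gene_body_fraction: float = 0.5
    promoter_window: int = 500
    min_replicates: int = 2
    min_summit: float = 10.0
    min_log2fc: float = 0.5
    negative_depth_threshold: float = 20.0
    negative_min_width: int = 20

    def validate(self) -> None:
        if not 0 <= self.hyperchip_percentile <= 100:
            raise ConfigurationError("hyperchip_percentile must be in [0, 100]")
        if not 0 < self.gene_body_fraction <= 1:
            raise ConfigurationError("gene_body_fraction must be in (0, 1]")
        if self.promoter_window <= 0 or self.min_replicates < 1:
            raise ConfigurationError("promoter_window/min_replicates invalid")
        if self.negative_depth_threshold <= 0 or self.negative_min_width <= 0:
            raise ConfigurationError("negative-peak thresholds must be > 0")


def classify_peak_context(region: GenomeInterval,
                          genes: Sequence[GeneModel],
                          promoter_window: int = 500,
                          gene_body_fraction: float = 0.5) -> PeakContext:
    """Label a region gene_body / promoter / intergenic.

    ``gene_body`` if the fraction of the region inside some gene body
    exceeds ``gene_body_fraction`` (gene with maximal overlap wins);
    otherwise ``promoter`` if the region overlaps the strand-aware
    ``promoter_window`` upstream of some TSS; otherwise ``intergenic``.
    """
    if promoter_window <= 0:
        raise ConfigurationError("promoter_window must be > 0")
    best_gene, best_frac = None, 0.0
    for g in genes:
        frac = interval_overlap_length(region, g.interval) / region.width
        if frac > best_frac:
            best_gene, best_frac = g, frac
    if best_gene is not None and best_frac > gene_body_fraction:
        return PeakContext("", GENE_BODY, best_gene.gene_id, best_frac)
    promoter_gene, promoter_ov = None, 0
    for g in genes:
        prom = g.promoter(promoter_window)
        if prom is None:
            continue
        ov = interval_overlap_length(region, prom)
        if ov > promoter_ov:
            promoter_gene, promoter_ov = g, ov
    if promoter_gene is not None:
        return PeakContext("", PROMOTER, promoter_gene.gene_id, best_frac)
    return PeakContext("", INTERGENIC, None, best_frac)


def expression_percentile(gene_fpkm: float, all_fpkm: Sequence[float]) -> float:
    """Mean-rank percentile of a gene's FPKM among all loci, in [0, 100].

    Ties take the mean rank of the tied group; the gene is assumed to be one
    of the loci in the reference distribution.
    """
    vals = np.asarray(all_fpkm, dtype=float)
    if vals.size == 0:
        raise UndefinedStatisticError("empty reference FPKM distribution")
    less = int(np.sum(vals < gene_fpkm))
    equal = int(np.sum(vals == gene_fpkm))
    if equal > 0:
        rank = less + (equal + 1) / 2.0
    else:
        rank = less + 0.5
    return 100.0 * rank / vals.size


@dataclass
class RegionConfidence:
    """Per-region screen outcome."""

    region_id: str
    context_label: str
    overlapped_gene: str | None
    expression_percentile: float
    hyperchip_flag: bool
    negative_flag: bool
    caller_support_ok: bool
    metric_support_ok: bool
    tier: str
    reason: str = ""


@dataclass
class ConfidenceReport:
    records: list[RegionConfidence]

    def tier(self, region_id: str) -> str:
        for rec in self.records:
            if rec.region_id == region_id:
                return rec.tier
        raise KeyError(region_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "region_id": r.region_id,
            "context": r.context_label,
            "overlapped_gene": r.overlapped_gene or ".",
            "expression_percentile": round(r.expression_percentile, 4),
            "hyperchip_flag": int(r.hyperchip_flag),
            "negative_flag": int(r.negative_flag),
            "caller_support_ok": int(r.caller_support_ok),
            "metric_support_ok": int(r.metric_support_ok),
            "tier": r.tier,
            "reason": r.reason or ".",
        } for r in self.records]
        return pd.DataFrame(
            rows, columns=["region_id", "context", "overlapped_gene",
                           "expression_percentile", "hyperchip_flag",
                           "negative_flag", "caller_support_ok",
                           "metric_support_ok", "tier", "reason"])

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def confidence_screen(regions: Sequence[ConsolidatedRegion],
                      contexts: Mapping[str, PeakContext],
                      condition_fpkm: pd.DataFrame,
                      all_callers: Iterable[str],
                      negative_regions: Sequence[GenomeInterval] = (),
                      config: ScreenConfig = ScreenConfig()) -> ConfidenceReport:
    """Combine artifact flags, support and metric thresholds into tiers.

    Parameters
    ----------
    contexts
        region_id -> :class:`PeakContext` (from :func:`classify_peak_context`).
    condition_fpkm
        genes x conditions FPKM table; the percentile reference per condition
        is the full gene set (all loci).
    all_callers
        The caller ids a high-confidence region must be supported by.
    negative_regions
        Detected input-over-ChIP intervals (any condition).
    """
    config.validate()
    all_callers = frozenset(all_callers)
    records = []
    for region in regions:
        ctx = contexts[region.region_id]
        negative = any(interval_overlap_length(region.interval, nr) > 0
                       for nr in negative_regions)
        region.negative_flag = negative

        # expression percentile of the overlapped gene, max across the
        # region's own (matched) conditions — conservative for flagging
        percentile = float("nan")
        if ctx.overlapped_gene is not None and ctx.overlapped_gene in condition_fpkm.index:
            matched = [c for c in region.metrics if c in condition_fpkm.columns]
            if not matched:
                matched = list(condition_fpkm.columns)
            percentile = max(
                expression_percentile(
                    float(condition_fpkm.at[ctx.overlapped_gene, c]),
                    condition_fpkm[c].to_numpy())
                for c in matched)

        hyperchip = (ctx.context_label == GENE_BODY
                     and np.isfinite(percentile)
                     and percentile >= config.hyperchip_percentile)
        region.hyperchip_flag = hyperchip

        caller_ok = region.caller_support == all_callers
        metric_ok = any(
            region.replicate_support.get(cond, 0) >= config.min_replicates
            and not m.degenerate
            and m.summit_height >= config.min_summit
            and m.pileup_log2fc >= config.min_log2fc
            for cond, m in region.metrics.items())

        if not region.metrics:
            tier, reason = TIER_REJECTED, "no signal"
        elif hyperchip or negative:
            tier = TIER_REJECTED
            reason = "hyperchip" if hyperchip else "negative peak"
        elif caller_ok and metric_ok:
            tier, reason = TIER_HIGH, ""
        else:
            tier, reason = TIER_AMBIGUOUS, "insufficient support or signal"

        records.append(RegionConfidence(
            region.region_id, ctx.context_label, ctx.overlapped_gene,
            percentile if np.isfinite(percentile) else float("nan"),
            hyperchip, negative, caller_ok, metric_ok, tier, reason))
    return ConfidenceReport(records)
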