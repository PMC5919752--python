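"""End-to-end orchestration: simulate -> consolidate -> metrics -> screen ->
correlate -> motif.

All final outputs are written atomically (write to a temporary file in the
same directory, then rename), so an interrupted run leaves no partially
written final artifacts.  Re-running with an identical configuration and
seed produces byte-identical TSV/BED outputs; timestamps are confined to the
run log.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import write_fasta, write_genes_gff3
from .coverage import CoverageTrack, diff_track, normalize_pair, write_bedgraph
from .errors import ConfigurationError, PeakScreenError, UndefinedStatisticError
from .expression import correlate_peak_expression
from .intervals import GeneModel, GenomeInterval
from .motif import (GibbsMotifSampler, logo_stats_table, scan_consensus,
                    write_pwm, write_sites_bed)
from .peaks import (ConsolidatedRegion, PeakCall, consolidate_peaks,
                    detect_negative_regions, metrics_table,
                    region_pileup_log2fc, region_summit_and_shape,
                    replicate_consensus_metrics, write_narrowpeak,
                    write_regions_bed)
from .screen import (ConfidenceReport, PeakContext, ScreenConfig, TIER_HIGH,
                     TIER_REJECTED, classify_peak_context, confidence_screen)
from .simulate import (HYPERCHIP, NEGATIVE, TRUE_PEAK, SimulationConfig,
                       SyntheticStudy, config_from_mapping, simulate_study)

logger = logging.getLogger("peakscreen")


@dataclass(frozen=True)
class MotifConfig:
    width: int = 8
    n_iterations: int = 200
    n_restarts: int = 5
    both_strands: bool = True
    scan_consensus: str = "CGGA"
    scan_both_strands: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    """One config to govern every stage; flags override file values."""

    out_dir: str = "peakscreen_out"
    seed: int = 1
    max_gap: int = 0
    pseudocount: float = 1.0
    write_tracks: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {k: raw[k] for k in raw
                        if k not in ("simulation", "screen", "motif")}
        sim = dict(raw.get("simulation", {}))
        sim.setdefault("seed", kwargs.get("seed", 1))
        kwargs["simulation"] = config_from_mapping(sim)
        screen_kwargs = dict(raw.get("screen", {}))
        kwargs["screen"] = ScreenConfig(**screen_kwargs)
        kwargs["motif"] = MotifConfig(**dict(raw.get("motif", {})))
        cfg = cls(**kwargs)
        cfg.screen.validate()
        return cfg

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = dataclasses.replace(self.simulation, seed=seed)
        return dataclasses.replace(self, seed=seed, simulation=sim)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def atomic_write(path: str | os.PathLike,
                 writer: Callable[[str], None]) -> None:
    """Write-then-rename: `writer` receives a temp path in the target dir."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    writer(str(tmp))
    os.replace(tmp, path)


def compute_region_metrics(
    regions: Sequence[ConsolidatedRegion],
    tracks: Mapping[tuple[str, str], tuple[CoverageTrack, CoverageTrack]],
    pseudocount: float = 1.0,
    negative_depth_threshold: float = 20.0,
    negative_min_width: int = 20,
) -> list[GenomeInterval]:
    """Fill per-condition replicate-averaged metrics on each region and
    return the detected negative regions (union over conditions).

    Metrics per replicate come from that replicate's normalized
    ChIP-minus-input difference; negative regions are detected on each
    condition's replicate-mean difference (averaging sharpens the
    input-over-ChIP signature against per-base noise).
    """
    by_condition: dict[str, list[tuple[str, CoverageTrack, CoverageTrack]]] = {}
    for (cond, rep), (chip, inp) in sorted(tracks.items()):
        by_condition.setdefault(cond, []).append((rep, chip, inp))

    negative_regions: list[GenomeInterval] = []
    per_region_cond: dict[tuple[int, str], list] = {}
    for cond, replicate_tracks in by_condition.items():
        diffs = []
        for rep, chip, inp in replicate_tracks:
            chip_n, inp_n = normalize_pair(chip, inp)
            d = diff_track(chip_n, inp_n)
            diffs.append(d)
            for k, region in enumerate(regions):
                m = region_summit_and_shape(region.interval, d)
                fc = region_pileup_log2fc(region.interval, chip_n, inp_n,
                                          pseudocount)
                m = dataclasses.replace(m, pileup_log2fc=fc)
                per_region_cond.setdefault((k, cond), []).append(m)
        mean_diff = CoverageTrack(
            {c: np.mean([d.values[c] for d in diffs], axis=0)
             for c in diffs[0].values},
            library_total=0.0, signed=True)
        negative_regions.extend(detect_negative_regions(
            mean_diff, negative_depth_threshold, negative_min_width))

    n_reps = {cond: len(v) for cond, v in by_condition.items()}
    for (k, cond), metric_list in per_region_cond.items():
        consensus, support = replicate_consensus_metrics(metric_list,
                                                         n_reps[cond])
        if consensus is not None:
            regions[k].metrics[cond] = consensus
    return negative_regions


@dataclass
class PipelineResult:
    study: SyntheticStudy
    regions: list[ConsolidatedRegion]
    contexts: dict[str, PeakContext]
    negative_regions: list[GenomeInterval]
    report: ConfidenceReport
    correlations: pd.DataFrame
    motif_model: object | None
    out_dir: Path


def _region_sequences(regions: Sequence[ConsolidatedRegion],
                      genome: Mapping[str, str],
                      report: ConfidenceReport) -> list[tuple[str, str, ConsolidatedRegion]]:
    seqs = []
    high = {r.region_id for r in report.records if r.tier == TIER_HIGH}
    for region in regions:
        if region.region_id in high:
            iv = region.interval
            seqs.append((region.region_id, genome[iv.chrom][iv.start:iv.end],
                         region))
    return seqs


def run_screen_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow on the configured synthetic study and write
    every artifact under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("peakscreen %s seed=%d config_hash=%s", __version__,
                    config.seed, config.config_hash())

        study = simulate_study(config.simulation)
        atomic_write(out / "genome.fa", lambda p: write_fasta(study.genome, p))
        atomic_write(out / "genes.gff3",
                     lambda p: write_genes_gff3(study.genes, p))
        atomic_write(out / "counts.tsv", study.expression.to_tsv)
        atomic_write(out / "true_fpkm.tsv",
                     lambda p: study.true_fpkm.to_csv(p, sep="\t",
                                                      index_label="gene_id"))
        atomic_write(out / "truth.tsv",
                     lambda p: study.truth.to_csv(p, sep="\t", index=False))
        atomic_write(out / "peak_calls.narrowPeak",
                     lambda p: write_narrowpeak(study.calls, p))
        atomic_write(out / "config.yaml", config.simulation.to_yaml)
        if config.write_tracks:
            for (cond, rep), (chip, inp) in sorted(study.tracks.items()):
                tag = f"{cond.replace(',', '_')}.{rep}"
                atomic_write(out / f"chip.{tag}.bedGraph",
                             lambda p, t=chip: write_bedgraph(t, p))
                atomic_write(out / f"input.{tag}.bedGraph",
                             lambda p, t=inp: write_bedgraph(t, p))

        regions = consolidate_peaks(study.calls, max_gap=config.max_gap)
        logger.info("consolidated %d calls into %d regions",
                    len(study.calls), len(regions))
        atomic_write(out / "regions.bed",
                     lambda p: write_regions_bed(regions, p))

        negative_regions = compute_region_metrics(
            regions, study.tracks, pseudocount=config.pseudocount,
            negative_depth_threshold=config.screen.negative_depth_threshold,
            negative_min_width=config.screen.negative_min_width)
        atomic_write(out / "metrics.tsv",
                     lambda p: metrics_table(regions).to_csv(p, sep="\t",
                                                             index=False))

        contexts = {}
        for region in regions:
            ctx = classify_peak_context(
                region.interval, study.genes,
                promoter_window=config.screen.promoter_window,
                gene_body_fraction=config.screen.gene_body_fraction)
            contexts[region.region_id] = dataclasses.replace(
                ctx, region_id=region.region_id)

        condition_fpkm = study.expression.condition_fpkm()
        atomic_write(out / "fpkm.tsv",
                     lambda p: condition_fpkm.to_csv(p, sep="\t",
                                                     index_label="gene_id"))
        report = confidence_screen(regions, contexts, condition_fpkm,
                                   all_callers=config.simulation.callers,
                                   negative_regions=negative_regions,
                                   config=config.screen)
        atomic_write(out / "confidence_report.tsv", report.write_tsv)
        high = [r for r in regions
                if report.tier(r.region_id) == TIER_HIGH]
        atomic_write(
            out / "high_confidence.bed",
            lambda p: write_regions_bed(high, p))
        logger.info("screen: %d/%d regions tier high", len(high), len(regions))

        # peak strength vs downstream-gene expression, across conditions
        corr_rows = []
        for region in high:
            gene = contexts[region.region_id].overlapped_gene
            if gene is None or gene not in condition_fpkm.index:
                continue
            fpkm_by_cond = condition_fpkm.loc[gene].to_dict()
            for metric in ("summit_height", "pileup_log2fc"):
                metric_by_cond = {c: getattr(m, metric)
                                  for c, m in region.metrics.items()}
                try:
                    res = correlate_peak_expression(metric_by_cond, fpkm_by_cond)
                except (UndefinedStatisticError, PeakScreenError):
                    continue
                corr_rows.append({"region_id": region.region_id,
                                  "metric": metric, "gene": gene,
                                  "r": res.r, "n": res.n,
                                  "p_two_sided": res.p_two_sided})
        correlations = pd.DataFrame(
            corr_rows, columns=["region_id", "metric", "gene", "r", "n",
                                "p_two_sided"])
        atomic_write(out / "correlations.tsv",
                     lambda p: correlations.to_csv(p, sep="\t", index=False))

        # motif discovery on the high-confidence region sequences
        motif_model = None
        region_seqs = _region_sequences(regions, study.genome, report)
        usable = [(rid, seq) for rid, seq, _ in region_seqs
                  if len(seq) >= config.motif.width]
        if len(usable) >= 2:
            sampler = GibbsMotifSampler(
                config.motif.width,
                n_iterations=config.motif.n_iterations,
                n_restarts=config.motif.n_restarts,
                both_strands=config.motif.both_strands,
                seed=config.seed)
            sampler.fit([s for _, s in usable],
                        sequence_ids=[rid for rid, _ in usable])
            motif_model = sampler.to_model()
            offsets = {rid: (region.interval.chrom, region.interval.start)
                       for rid, _, region in region_seqs}
            atomic_write(out / "motif_pwm.tsv",
                         lambda p: write_pwm(motif_model.pwm, p))
            atomic_write(out / "motif_sites.bed",
                         lambda p: write_sites_bed(motif_model.sites,
                                                   motif_model.width, p,
                                                   region_offsets=offsets))
            stats = logo_stats_table(sampler.site_sequences_,
                                     background=sampler.background_,
                                     seed=config.seed)
            atomic_write(out / "motif_logo_stats.tsv",
                         lambda p: stats.to_csv(p, sep="\t", index=False))
            hits = scan_consensus([(rid, s) for rid, s in usable],
                                  config.motif.scan_consensus,
                                  both_strands=config.motif.scan_both_strands)
            atomic_write(out / "motif_scan.bed",
                         lambda p: write_sites_bed(
                             hits, len(config.motif.scan_consensus), p,
                             region_offsets=offsets))
        logger.info("pipeline complete: %s", out)
        return PipelineResult(study, regions, contexts, negative_regions,
                              report, correlations, motif_model, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def evaluate_against_truth(result: PipelineResult) -> dict[str, float]:
    """Score the screen's tier assignments against the planted truth.

    * sensitivity: true peaks whose best-overlapping region is tier high.
    * artifact_flag_rate: hyper-ChIPable + negative objects whose
      best-overlapping region is rejected.
    * summit_within_25bp_rate: detected true peaks whose condition-mean
      summit position is within 25 bp of the planted center.
    * tier_accuracy: all planted objects whose matched region has the
      expected tier.
    """
    from .intervals import interval_overlap_length

    regions = result.regions
    tiers = {rec.region_id: rec.tier for rec in result.report.records}

    def best_region(row) -> ConsolidatedRegion | None:
        iv = GenomeInterval(row.chrom, row.start, row.end)
        best, best_ov = None, 0
        for r in regions:
            ov = interval_overlap_length(iv, r.interval)
            if ov > best_ov:
                best, best_ov = r, ov
        return best

    truth = result.study.truth
    n_true = n_true_high = 0
    n_art = n_art_rejected = 0
    n_detected = n_summit_ok = 0
    n_correct = 0
    for row in truth.itertuples():
        region = best_region(row)
        tier = tiers.get(region.region_id) if region is not None else None
        if row.kind == TRUE_PEAK:
            n_true += 1
            if tier == TIER_HIGH:
                n_true_high += 1
                n_correct += 1
            if region is not None and region.metrics:
                n_detected += 1
                positions = [region.interval.start + m.summit_offset
                             for m in region.metrics.values()]
                if abs(float(np.mean(positions)) - row.center) <= 25:
                    n_summit_ok += 1
        else:
            n_art += 1
            if tier == TIER_REJECTED:
                n_art_rejected += 1
                n_correct += 1
    total = n_true + n_art
    return {
        "sensitivity": n_true_high / n_true if n_true else float("nan"),
        "artifact_flag_rate": n_art_rejected / n_art if n_art else float("nan"),
        "summit_within_25bp_rate": (n_summit_ok / n_detected
                                    if n_detected else float("nan")),
        "tier_accuracy": n_correct / total if total else float("nan"),
        "n_true_peaks": float(n_true),
        "n_artifacts": float(n_art),
    }
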