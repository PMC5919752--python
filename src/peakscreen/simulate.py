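"""Self-contained synthetic study generator.

Emulates the data structure of an allele-by-medium yeast TF ChIP-Seq/RNA-Seq
study: a small uniform-base genome with spaced gene models, log-normal gene
expression with per-condition effects and Poisson-sampled counts, and
replicate ChIP/input per-base pileups containing

* true TF peaks — Gaussian bumps planted within the promoter window
  upstream of selected TSSs (with a degenerate motif written into the
  genome at the bump center),
* hyper-ChIPable artifacts — gene-body signal proportional to true FPKM
  over the most-expressed genes (a tight, very highly expressed cohort,
  emulating ribosomal-gene-level loci),
* negative peaks — Gaussian bumps added to the *input* track only.

Noisy two-caller peak calls are emulated around the planted objects so the
consolidation step has caller output to consume.  Every generator is a pure
function of its configuration (bit-identical reruns for the same seed), and
a truth table records each planted object for downstream evaluation.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coverage import CoverageTrack
from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .intervals import GeneModel, GenomeInterval
from .peaks import PeakCall
from .sequences import BASES, revcomp

DEFAULT_CONDITIONS = (
    "S96,YPD", "S96,4NQO",
    "S96-I775E,YPD", "S96-I775E,4NQO",
    "YJM789,YPD", "YJM789,4NQO",
)

TRUE_PEAK = "true_peak"
HYPERCHIP = "hyperchip_artifact"
NEGATIVE = "negative_peak"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the structure of the emulated study: six allele-by-medium
    conditions, three ChIP replicates and two RNA replicates per condition,
    ~1 Mbp-scale yeast-like gene density scaled to a 200 kb test chromosome.
    """

    seed: int = 1
    chromosomes: tuple[tuple[str, int], ...] = (("chrI", 200_000),)
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (1000, 2000)
    min_intergenic: int = 1000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_rna_replicates: int = 2
    n_chip_replicates: int = 3
    # expression model: log-normal FPKM with multiplicative condition effects
    expression_meanlog: float = 3.0
    expression_sdlog: float = 1.2
    condition_effect_sdlog: float = 0.4
    hyperchip_meanlog: float = 6.2
    hyperchip_sdlog: float = 0.25
    rna_depth: int = 1_000_000
    # ChIP model
    background: float = 10.0
    n_true_peaks: int = 10
    peak_amplitude_range: tuple[float, float] = (150.0, 250.0)
    peak_sd_bp: int = 50
    promoter_offset_range: tuple[int, int] = (50, 450)
    n_hyperchip: int = 10
    hyperchip_coef: float = 0.5
    n_negative_peaks: int = 5
    negative_amplitude: float = 100.0
    negative_sd_bp: int = 50
    # planted motif
    motif_consensus: str = "TTCGGAAT"
    motif_mutation_rate: float = 0.1
    # emulated caller output
    callers: tuple[str, ...] = ("cisgenome", "macs2")
    call_detection_prob: float = 0.9
    call_halfwidth: int = 100
    call_jitter: int = 30

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_true_peaks < 0 or self.n_hyperchip < 0:
            raise ConfigurationError("counts must be >= 0")
        if not 0 <= self.motif_mutation_rate <= 1:
            raise ConfigurationError("mutation rate must be in [0, 1]")
        if not 0 <= self.call_detection_prob <= 1:
            raise ConfigurationError("detection prob must be in [0, 1]")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.n_hyperchip + self.n_true_peaks > self.n_genes:
            raise ConfigurationError(
                "need n_genes >= n_true_peaks + n_hyperchip")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return config_from_mapping(raw)


def config_from_mapping(raw: Mapping) -> SimulationConfig:
    """Build a config from a plain mapping (YAML), restoring tuple fields."""
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    for f in dataclasses.fields(SimulationConfig):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if f.name == "chromosomes":
            v = tuple((str(c), int(n)) for c, n in v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_reference(config: SimulationConfig
                       ) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-base chromosomes with non-overlapping, well-spaced genes."""
    config.validate()
    rng = _stage_rng(config, 0)
    genome = {
        name: "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        for name, length in config.chromosomes
    }
    # allocate genes to chromosomes proportionally to length
    names = [c for c, _ in config.chromosomes]
    lengths = np.array([n for _, n in config.chromosomes], dtype=float)
    counts = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    for i in range(config.n_genes - counts.sum()):
        counts[i % len(counts)] += 1

    genes: list[GeneModel] = []
    gidx = 0
    lo, hi = config.gene_length_range
    for (chrom, chrom_len), n_here in zip(config.chromosomes, counts):
        if n_here == 0:
            continue
        gene_lens = rng.integers(lo, hi + 1, size=n_here)
        needed = int(gene_lens.sum()) + (n_here + 1) * config.min_intergenic
        slack = chrom_len - needed
        if slack < 0:
            raise ConfigurationError(
                f"{chrom}: cannot place {n_here} genes of {lo}-{hi} bp with "
                f"{config.min_intergenic} bp spacing on {chrom_len} bp")
        extra = rng.multinomial(slack, np.full(n_here + 1, 1.0 / (n_here + 1)))
        pos = 0
        for k in range(n_here):
            pos += config.min_intergenic + int(extra[k])
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomeInterval(chrom, pos, pos + int(gene_lens[k]), strand)
            genes.append(GeneModel(f"gene{gidx:04d}", iv))
            gidx += 1
            pos = iv.end
    return genome, genes


def simulate_expression_counts(genes: Sequence[GeneModel],
                               config: SimulationConfig
                               ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-normal true FPKM with condition effects; Poisson counts.

    count ~ Poisson(trueFPKM * length_kb * depth / 1e6); the designated
    hyper-ChIPable cohort draws its base expression from a tight, very high
    log-normal so it forms the most-expressed gene set.
    """
    config.validate()
    rng = _stage_rng(config, 1)
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)
    base = rng.lognormal(config.expression_meanlog, config.expression_sdlog,
                         size=n)
    hyper_idx = rng.choice(n, size=min(config.n_hyperchip, n), replace=False)
    base[hyper_idx] = rng.lognormal(config.hyperchip_meanlog,
                                    config.hyperchip_sdlog,
                                    size=hyper_idx.size)
    effects = rng.lognormal(0.0, config.condition_effect_sdlog,
                            size=(n, len(config.conditions)))
    true_fpkm = pd.DataFrame(base[:, None] * effects, index=gene_ids,
                             columns=list(config.conditions))

    lengths = pd.Series([g.length_bp for g in genes], index=gene_ids)
    samples, sample_condition = [], {}
    counts = {}
    for cond in config.conditions:
        for r in range(1, config.n_rna_replicates + 1):
            sample = f"{cond}|rna{r}"
            samples.append(sample)
            sample_condition[sample] = cond
            lam = (true_fpkm[cond].to_numpy() * (lengths.to_numpy() / 1000.0)
                   * config.rna_depth / 1.0e6)
            counts[sample] = rng.poisson(lam)
    count_df = pd.DataFrame(counts, index=gene_ids)[samples]
    lib = pd.Series(float(config.rna_depth), index=samples)
    em = ExpressionMatrix(count_df, lengths, lib, sample_condition)
    return em, true_fpkm


def _gaussian_bump(length: int, center: int, amplitude: float,
                   sd: float) -> np.ndarray:
    x = np.arange(length, dtype=float)
    return amplitude * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate_chip_tracks(genes: Sequence[GeneModel],
                         true_fpkm: pd.DataFrame,
                         config: SimulationConfig,
                         ) -> tuple[dict[tuple[str, str], tuple[CoverageTrack, CoverageTrack]], pd.DataFrame]:
    """Replicate ChIP/input pileups with planted objects, plus a truth table.

    Per condition and replicate: input = Poisson(background) noise plus the
    negative-peak bumps; ChIP = Poisson(background) noise plus the true-peak
    bumps and the hyper-ChIPable gene-body signal (hyperchip_coef x that
    condition's true FPKM).  Replicates share the planted truth and have
    independent noise.
    """
    config.validate()
    rng = _stage_rng(config, 2)
    chrom_lengths = dict(config.chromosomes)
    genes_by_id = {g.gene_id: g for g in genes}

    order = true_fpkm.mean(axis=1).sort_values(ascending=False)
    hyper_genes = list(order.index[:config.n_hyperchip])

    # true peaks upstream of non-hyperchip genes
    candidates = [g for g in genes if g.gene_id not in set(hyper_genes)]
    if len(candidates) < config.n_true_peaks:
        raise ConfigurationError("not enough genes for the requested true peaks")
    pick = rng.choice(len(candidates), size=config.n_true_peaks, replace=False)

    truth_rows = []
    occupied: list[GenomeInterval] = [g.interval for g in genes]
    lo_amp, hi_amp = config.peak_amplitude_range
    lo_off, hi_off = config.promoter_offset_range
    for idx in pick:
        g = candidates[idx]
        offset = int(rng.integers(lo_off, hi_off + 1))
        center = g.tss - offset if g.interval.strand != "-" else g.tss + offset
        center = int(np.clip(center, 3 * config.peak_sd_bp,
                             chrom_lengths[g.interval.chrom] - 3 * config.peak_sd_bp))
        amp = float(rng.uniform(lo_amp, hi_amp))
        span = GenomeInterval(g.interval.chrom,
                              max(0, center - 3 * config.peak_sd_bp),
                              center + 3 * config.peak_sd_bp)
        occupied.append(span)
        truth_rows.append({"kind": TRUE_PEAK, "chrom": span.chrom,
                           "start": span.start, "end": span.end,
                           "center": center, "amplitude": amp,
                           "gene_id": g.gene_id})

    for gid in hyper_genes:
        g = genes_by_id[gid]
        truth_rows.append({"kind": HYPERCHIP, "chrom": g.interval.chrom,
                           "start": g.interval.start, "end": g.interval.end,
                           "center": (g.interval.start + g.interval.end) // 2,
                           "amplitude": float(config.hyperchip_coef
                                              * true_fpkm.loc[gid].mean()),
                           "gene_id": gid})

    # negative peaks in free intergenic space, redrawn on collision
    margin = 3 * config.negative_sd_bp
    chroms = [c for c, _ in config.chromosomes]
    probs = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    for _ in range(config.n_negative_peaks):
        for attempt in range(200):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            center = int(rng.integers(margin, chrom_lengths[chrom] - margin))
            span = GenomeInterval(chrom, center - margin, center + margin)
            if not any(span.chrom == o.chrom and span.start < o.end
                       and o.start < span.end for o in occupied):
                break
        else:
            raise ConfigurationError(
                "could not place negative peaks without collisions")
        occupied.append(span)
        truth_rows.append({"kind": NEGATIVE, "chrom": chrom,
                           "start": span.start, "end": span.end,
                           "center": center,
                           "amplitude": float(config.negative_amplitude),
                           "gene_id": ""})

    truth = pd.DataFrame(truth_rows, columns=["kind", "chrom", "start", "end",
                                              "center", "amplitude", "gene_id"])

    # deterministic signal fields
    neg_field = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for row in truth[truth.kind == NEGATIVE].itertuples():
        neg_field[row.chrom] += _gaussian_bump(
            chrom_lengths[row.chrom], row.center, row.amplitude,
            config.negative_sd_bp)

    chip_field = {cond: {c: np.zeros(n) for c, n in chrom_lengths.items()}
                  for cond in config.conditions}
    for row in truth[truth.kind == TRUE_PEAK].itertuples():
        bump = _gaussian_bump(chrom_lengths[row.chrom], row.center,
                              row.amplitude, config.peak_sd_bp)
        for cond in config.conditions:
            chip_field[cond][row.chrom] += bump
    for gid in hyper_genes:
        g = genes_by_id[gid]
        for cond in config.conditions:
            chip_field[cond][g.interval.chrom][g.interval.start:g.interval.end] += (
                config.hyperchip_coef * float(true_fpkm.at[gid, cond]))

    # libraries are sequenced to a common nominal depth, so planted
    # amplitudes are already in normalized (depth-matched) units
    nominal_depth = config.background * sum(chrom_lengths.values())
    tracks: dict[tuple[str, str], tuple[CoverageTrack, CoverageTrack]] = {}
    for cond in config.conditions:
        for r in range(1, config.n_chip_replicates + 1):
            chip_vals, input_vals = {}, {}
            for chrom, n in chrom_lengths.items():
                chip_vals[chrom] = (rng.poisson(config.background, n)
                                    + chip_field[cond][chrom])
                input_vals[chrom] = (rng.poisson(config.background, n)
                                     + neg_field[chrom])
            tracks[(cond, f"rep{r}")] = (
                CoverageTrack(chip_vals, library_total=nominal_depth),
                CoverageTrack(input_vals, library_total=nominal_depth))
    return tracks, truth


def mutate_consensus(consensus: str, mutation_rate: float,
                     rng: np.random.Generator) -> str:
    """Copy of the consensus with i.i.d. per-position substitutions to one
    of the three non-consensus bases."""
    out = []
    for b in consensus:
        if rng.random() < mutation_rate:
            alternatives = [x for x in BASES if x != b]
            out.append(alternatives[int(rng.integers(0, 3))])
        else:
            out.append(b)
    return "".join(out)


def plant_truth_motifs(genome: dict[str, str], truth: pd.DataFrame,
                       config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Write a mutated consensus copy into the genome at each true-peak
    center; returns the edited genome and truth with motif columns added."""
    rng = _stage_rng(config, 3)
    genome = dict(genome)
    w = len(config.motif_consensus)
    offsets, strands = [], []
    for row in truth.itertuples():
        if row.kind != TRUE_PEAK:
            offsets.append(-1)
            strands.append(".")
            continue
        inst = mutate_consensus(config.motif_consensus,
                                config.motif_mutation_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            inst = revcomp(inst)
        start = row.center - w // 2
        seq = genome[row.chrom]
        genome[row.chrom] = seq[:start] + inst + seq[start + w:]
        offsets.append(start)
        strands.append(strand)
    truth = truth.copy()
    truth["motif_offset"] = offsets
    truth["motif_strand"] = strands
    return genome, truth


def plant_motif_sequences(n_sequences: int, length: int, consensus: str,
                          mutation_rate: float, seed: int,
                          both_strands: bool = False
                          ) -> tuple[list[str], list[int], list[str]]:
    """Uniform-random sequences, each with one mutated consensus copy at a
    uniform random offset (strand sampled uniformly when enabled)."""
    w = len(consensus)
    if length < w:
        raise ConfigurationError("sequence length shorter than consensus")
    if not 0 <= mutation_rate <= 1:
        raise ConfigurationError("mutation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs, offsets, strands = [], [], []
    for _ in range(n_sequences):
        s = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        inst = mutate_consensus(consensus, mutation_rate, rng)
        strand = "+"
        if both_strands and rng.random() < 0.5:
            strand = "-"
            inst = revcomp(inst)
        off = int(rng.integers(0, length - w + 1))
        seqs.append(s[:off] + inst + s[off + w:])
        offsets.append(off)
        strands.append(strand)
    return seqs, offsets, strands


def simulate_peak_calls(truth: pd.DataFrame,
                        config: SimulationConfig) -> list[PeakCall]:
    """Noisy two-caller call emulation around every planted object.

    Each caller x condition x replicate detects each object with
    ``call_detection_prob`` and reports jittered boundaries.  True peaks and
    negative-peak loci get calls around the planted center; hyper-ChIPable
    artifacts get calls spanning the gene body.
    """
    config.validate()
    rng = _stage_rng(config, 4)
    calls: list[PeakCall] = []
    chrom_lengths = dict(config.chromosomes)
    for row in truth.itertuples():
        for cond in config.conditions:
            for r in range(1, config.n_chip_replicates + 1):
                for caller in config.callers:
                    if rng.random() >= config.call_detection_prob:
                        continue
                    if row.kind == HYPERCHIP:
                        start = row.start + int(rng.integers(-config.call_jitter,
                                                             config.call_jitter + 1))
                        end = row.end + int(rng.integers(-config.call_jitter,
                                                         config.call_jitter + 1))
                    else:
                        start = (row.center - config.call_halfwidth
                                 + int(rng.integers(-config.call_jitter,
                                                    config.call_jitter + 1)))
                        end = (row.center + config.call_halfwidth
                               + int(rng.integers(-config.call_jitter,
                                                  config.call_jitter + 1)))
                    start = max(0, start)
                    end = min(chrom_lengths[row.chrom], end)
                    if end <= start:
                        continue
                    iv = GenomeInterval(row.chrom, start, end)
                    calls.append(PeakCall(iv, caller, f"rep{r}", cond,
                                          float(rng.uniform(1, 100))))
    return calls


@dataclass
class SyntheticStudy:
    """The full synthetic study bundle."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    expression: ExpressionMatrix
    true_fpkm: pd.DataFrame
    tracks: dict[tuple[str, str], tuple[CoverageTrack, CoverageTrack]]
    calls: list[PeakCall]
    truth: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.config.chromosomes)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage in order, sharing one seeded config."""
    genome, genes = simulate_reference(config)
    expression, true_fpkm = simulate_expression_counts(genes, config)
    tracks, truth = simulate_chip_tracks(genes, true_fpkm, config)
    genome, truth = plant_truth_motifs(genome, truth, config)
    calls = simulate_peak_calls(truth, config)
    return SyntheticStudy(config, genome, genes, expression, true_fpkm,
                          tracks, calls, truth)
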