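"""Gene expression quantification and peak–expression correlation.

FPKM (fragments per kilobase of gene per million mapped fragments) is
computed per replicate sample from a count table; per-condition FPKM is the
mean over that condition's replicates.  Library sizes are the mapped-fragment
totals *after* removing excluded classes (rRNA/tRNA, which are extracted at
high and variable abundance and would bias the denominator).

Pearson's correlation between a peak metric and the expression of a nearby
gene across conditions is computed with ``scipy.stats.pearsonr``.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ShapeError, UndefinedStatisticError


def compute_fpkm(count: float, gene_length_bp: int, library_size: float) -> float:
    """count * 1e9 / (length_bp * library_size).

    Exactly invariant to scaling count and library size by the same factor.
    """
    if gene_length_bp <= 0:
        raise ConfigurationError("gene length must be > 0")
    if library_size <= 0:
        raise ConfigurationError("library size must be > 0")
    return count * 1.0e9 / (gene_length_bp * library_size)


def log2fc_fpkm(fpkm_num: float, fpkm_den: float, pseudo: float = 0.0) -> float:
    """log2((num + pseudo) / (den + pseudo)).

    With the default pseudo of 0 a zero numerator or denominator is an error
    rather than being silently floored.
    """
    if pseudo < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    num, den = fpkm_num + pseudo, fpkm_den + pseudo
    if num <= 0 or den <= 0:
        raise UndefinedStatisticError(
            "log2 fold change undefined for non-positive FPKM without a "
            "pseudocount"
        )
    # log2(num) - log2(den): exactly antisymmetric under argument swap
    return math.log2(num) - math.log2(den)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value (n-2 degrees of freedom)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ShapeError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 3:
        raise ShapeError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(float(res.statistic), int(xa.size), float(res.pvalue))


class ExpressionMatrix:
    """Gene x sample counts with the metadata needed for FPKM.

    Parameters
    ----------
    counts
        DataFrame, genes as index, samples as columns, non-negative integers.
    gene_lengths
        bp per gene (Series aligned to the count index).
    library_sizes
        Mapped-fragment total per sample, after exclusion-class removal.
    sample_condition
        sample name -> condition id.
    excluded_classes
        Gene classes removed from library totals (bookkeeping only).
    """

    def __init__(self, counts: pd.DataFrame, gene_lengths: pd.Series,
                 library_sizes: pd.Series,
                 sample_condition: Mapping[str, str],
                 excluded_classes: frozenset[str] = frozenset({"rRNA", "tRNA"})):
        self.counts = counts
        self.gene_lengths = gene_lengths.reindex(counts.index)
        self.library_sizes = library_sizes.reindex(counts.columns)
        self.sample_condition = dict(sample_condition)
        self.excluded_classes = frozenset(excluded_classes)
        if (self.gene_lengths <= 0).any():
            raise ConfigurationError("all gene lengths must be > 0")
        if (self.library_sizes <= 0).any():
            raise ConfigurationError("all library sizes must be > 0")
        missing = set(counts.columns) - set(self.sample_condition)
        if missing:
            raise ConfigurationError(f"samples without a condition: {missing}")

    def fpkm(self) -> pd.DataFrame:
        """Per-sample FPKM (genes x samples)."""
        return (self.counts * 1.0e9).div(self.gene_lengths, axis=0).div(
            self.library_sizes, axis=1)

    def condition_fpkm(self) -> pd.DataFrame:
        """Per-condition FPKM: mean over each condition's replicate samples."""
        f = self.fpkm()
        groups = pd.Series(self.sample_condition).reindex(f.columns)
        return f.T.groupby(groups).mean().T

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.counts.copy()
        df.insert(0, "length_bp", self.gene_lengths)
        df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike,
                 library_sizes: Mapping[str, float],
                 sample_condition: Mapping[str, str]) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        df.index.name = None
        lengths = df.pop("length_bp")
        return cls(df, lengths, pd.Series(library_sizes), sample_condition)


@dataclass(frozen=True)
class ExpressionContrast:
    numerator_condition: str
    denominator_condition: str
    log2fc: pd.Series  # per gene


def contrast_conditions(condition_fpkm: pd.DataFrame, numerator: str,
                        denominator: str, pseudo: float = 0.0) -> ExpressionContrast:
    """Per-gene log2 fold change of FPKM between two conditions.

    A self-contrast is exactly zero for every gene.
    """
    for cond in (numerator, denominator):
        if cond not in condition_fpkm.columns:
            raise ConfigurationError(f"unknown condition {cond!r}")
    num = condition_fpkm[numerator] + pseudo
    den = condition_fpkm[denominator] + pseudo
    if ((num <= 0) | (den <= 0)).any():
        raise UndefinedStatisticError(
            "zero FPKM encountered with no pseudocount")
    fc = np.log2(num) - np.log2(den)
    if numerator == denominator:
        fc = fc * 0.0
    return ExpressionContrast(numerator, denominator, fc.rename("log2fc"))


def correlate_peak_expression(metric_by_condition: Mapping[str, float],
                              fpkm_by_condition: Mapping[str, float],
                              conditions: Sequence[str] | None = None) -> CorrelationResult:
    """Correlate a per-condition peak metric with a gene's per-condition FPKM.

    ``conditions`` selects and orders the condition grouping used for the
    test; by default all conditions present in both inputs, sorted.
    """
    if conditions is None:
        conditions = sorted(set(metric_by_condition) & set(fpkm_by_condition))
    x = [metric_by_condition[c] for c in conditions]
    y = [fpkm_by_condition[c] for c in conditions]
    return pearson_correlation(x, y)
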