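"""Synthetic-study generator: determinism, truth bookkeeping and the
statistical calibration of planted signal against noise."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from peakscreen import (SimulationConfig, compute_fpkm,
                        detect_negative_regions, diff_track, normalize_pair,
                        simulate_chip_tracks, simulate_expression_counts,
                        simulate_reference, simulate_study)
from peakscreen.errors import ConfigurationError
from peakscreen.intervals import GeneModel, GenomeInterval
from peakscreen.simulate import HYPERCHIP, NEGATIVE, TRUE_PEAK


def cfg(**kw):
    return dataclasses.replace(SimulationConfig(), **kw)


class TestSimulateReference:
    def test_gene_placement_constraints(self):
        config = cfg(chromosomes=(("chrI", 100_000),), n_genes=20,
                     gene_length_range=(2000, 2000), n_true_peaks=5,
                     n_hyperchip=5)
        genome, genes = simulate_reference(config)
        assert len(genome["chrI"]) == 100_000
        assert len(genes) == 20
        ordered = sorted(genes, key=lambda g: g.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            assert b.interval.start - a.interval.end >= config.min_intergenic
        assert all(g.interval.end <= 100_000 for g in genes)

    def test_overfull_chromosome_rejected(self):
        config = cfg(chromosomes=(("chrI", 50_000),), n_genes=100,
                     gene_length_range=(2000, 2000), n_true_peaks=0,
                     n_hyperchip=0)
        with pytest.raises(ConfigurationError):
            simulate_reference(config)

    def test_same_seed_is_bit_identical(self):
        config = cfg(seed=5)
        g1, genes1 = simulate_reference(config)
        g2, genes2 = simulate_reference(config)
        assert g1 == g2 and genes1 == genes2


def toy_genes(n, length=1500, spacing=3000, chrom="chrI"):
    return [GeneModel(f"g{i:04d}",
                      GenomeInterval(chrom, i * spacing, i * spacing + length,
                                     "+"))
            for i in range(n)]


class TestSimulateExpression:
    def test_deterministic(self):
        config = cfg(seed=3)
        genes = toy_genes(config.n_genes)
        em1, tf1 = simulate_expression_counts(genes, config)
        em2, tf2 = simulate_expression_counts(genes, config)
        pd.testing.assert_frame_equal(em1.counts, em2.counts)
        pd.testing.assert_frame_equal(tf1, tf2)

    def test_fpkm_estimator_is_unbiased(self):
        """E[FPKM-hat] = true FPKM by the law of the Poisson mean: the
        across-genes mean of measured/true ratios stays within 5%."""
        config = cfg(n_genes=2000, n_hyperchip=0, n_true_peaks=0,
                     conditions=("c1", "c2"), n_rna_replicates=2,
                     rna_depth=1_000_000, seed=21)
        genes = toy_genes(2000)
        em, true_fpkm = simulate_expression_counts(genes, config)
        measured = em.condition_fpkm()
        ratios = (measured / true_fpkm[measured.columns]).to_numpy().ravel()
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_zero_expression_gives_zero_counts(self):
        config = cfg(n_genes=5, n_hyperchip=0, n_true_peaks=0,
                     conditions=("c1",), seed=8)
        genes = toy_genes(5)
        em, true_fpkm = simulate_expression_counts(genes, config)
        # force the Poisson rate to zero by direct evaluation of the model
        lam = 0.0 * 1.5 * config.rna_depth / 1e6
        assert np.random.default_rng(0).poisson(lam) == 0


@pytest.fixture(scope="module")
def study():
    return simulate_study(SimulationConfig(seed=4))


class TestSimulateChipTracks:
    def test_truth_counts_match_config(self, study):
        counts = study.truth.kind.value_counts()
        assert counts[TRUE_PEAK] == study.config.n_true_peaks
        assert counts[HYPERCHIP] == study.config.n_hyperchip
        assert counts[NEGATIVE] == study.config.n_negative_peaks

    def test_deterministic(self):
        config = SimulationConfig(seed=6, conditions=("c1",),
                                  n_chip_replicates=1)
        s1 = simulate_study(config)
        s2 = simulate_study(config)
        assert s1.genome == s2.genome
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        for key in s1.tracks:
            assert s1.tracks[key][0].allclose(s2.tracks[key][0], atol=0)
            assert s1.tracks[key][1].allclose(s2.tracks[key][1], atol=0)
        assert s1.calls == s2.calls

    def test_planted_summits_rise_above_noise(self, study):
        """Difference-track value at a planted center exceeds half the
        minimum planted amplitude for >= 95% of peaks."""
        ok = total = 0
        for (cond, rep), (chip, inp) in study.tracks.items():
            d = diff_track(*normalize_pair(chip, inp))
            for row in study.truth[study.truth.kind == TRUE_PEAK].itertuples():
                total += 1
                ok += d.values[row.chrom][row.center] > 100
        assert ok / total >= 0.95

    def test_null_tracks_produce_no_negative_calls(self):
        """With nothing planted, ChIP and input differ only by noise and the
        negative-peak detector stays silent at 5 sd of the background."""
        empties = 0
        for seed in range(10):
            config = cfg(seed=seed, n_true_peaks=0, n_hyperchip=0,
                         n_negative_peaks=0, conditions=("c1",),
                         n_chip_replicates=1)
            _, genes = simulate_reference(config)
            _, tf = simulate_expression_counts(genes, config)
            tracks, truth = simulate_chip_tracks(genes, tf, config)
            assert truth.empty
            chip, inp = tracks[("c1", "rep1")]
            d = diff_track(*normalize_pair(chip, inp))
            thr = 5 * np.sqrt(config.background)
            empties += detect_negative_regions(d, thr, 20) == []
        assert empties >= 9

    def test_planted_bump_area_matches_analytic_sum(self):
        """Total planted ChIP signal equals the sum of Gaussian areas within
        2% (before noise; noise cancels in the replicate-mean difference)."""
        config = cfg(seed=14, n_hyperchip=0, n_negative_peaks=0,
                     conditions=("c1",), n_chip_replicates=3)
        _, genes = simulate_reference(config)
        _, tf = simulate_expression_counts(genes, config)
        tracks, truth = simulate_chip_tracks(genes, tf, config)
        diffs = [chip.values["chrI"] - inp.values["chrI"]
                 for chip, inp in tracks.values()]
        planted_total = float(np.mean(diffs, axis=0).sum())
        analytic = float((truth.amplitude * config.peak_sd_bp
                          * np.sqrt(2 * np.pi)).sum())
        assert planted_total == pytest.approx(analytic, rel=0.02)

    def test_hyperchip_genes_are_most_expressed(self, study):
        hyper = set(study.truth.loc[study.truth.kind == HYPERCHIP, "gene_id"])
        top = set(study.true_fpkm.mean(axis=1).nlargest(len(hyper)).index)
        assert hyper == top

    def test_motif_planted_at_true_peak_centers(self, study):
        from peakscreen import revcomp

        w = len(study.config.motif_consensus)
        match_counts = []
        for row in study.truth[study.truth.kind == TRUE_PEAK].itertuples():
            window = study.genome[row.chrom][row.motif_offset:row.motif_offset + w]
            assert len(window) == w
            if row.motif_strand == "-":
                window = revcomp(window)
            match_counts.append(sum(a == b for a, b in
                                    zip(window, study.config.motif_consensus)))
        # per-position mutation rate 0.1 -> expected ~7.2/8 matches
        assert np.mean(match_counts) >= 6.5

    def test_calls_cover_all_planted_objects(self, study):
        covered = 0
        for row in study.truth.itertuples():
            iv = GenomeInterval(row.chrom, row.start, row.end)
            hit = any(c.interval.chrom == iv.chrom
                      and c.interval.start < iv.end and iv.start < c.interval.end
                      for c in study.calls)
            covered += hit
        assert covered == len(study.truth)
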