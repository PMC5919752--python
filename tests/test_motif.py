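"""PWM construction, logo entropy statistics, consensus scanning and the
Gibbs site sampler."""
import numpy as np
import pytest

from peakscreen import (GibbsMotifSampler, column_relative_entropy_ci,
                        gibbs_motif_sampler, plant_motif_sequences,
                        point_relative_entropy, pwm_from_sites, revcomp,
                        scan_consensus)
from peakscreen.errors import ConfigurationError, SequenceError

UNIFORM = np.full(4, 0.25)

# Motif-1 sequences of the three published high-confidence regions
MOTIF1_14MERS = ["TAAACGGAAATGGG", "TCATCGGAATTGAG", "TACACGGAAATAGG"]


class TestPwmFromSites:
    def test_identical_sites_no_pseudocount(self):
        pwm = pwm_from_sites(["CGGA"] * 3, pseudocount=0.0)
        for j, base_idx in enumerate([1, 2, 2, 0]):  # C, G, G, A
            assert pwm[j, base_idx] == 1.0
            assert pwm[j].sum() == pytest.approx(1.0)

    def test_uniform_pseudocount_value(self):
        pwm = pwm_from_sites(["CGGA"] * 3, pseudocount=0.25,
                             background=UNIFORM)
        # (3 + 0.25) / (3 + 1)
        assert pwm[0, 1] == pytest.approx(0.8125)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            pwm_from_sites(["CGGA", "CGG"])

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            pwm_from_sites([])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        sites = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(9)]
        pwm = pwm_from_sites(sites, pseudocount=0.5)
        assert np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9)
        assert (pwm >= 0).all()


class TestRelativeEntropy:
    def test_uniform_vs_uniform_is_zero(self):
        assert point_relative_entropy(UNIFORM, UNIFORM) == 0.0

    def test_point_mass_vs_uniform_is_two_bits(self):
        assert point_relative_entropy([1, 0, 0, 0], UNIFORM) == 2.0

    def test_half_half_is_one_bit(self):
        assert point_relative_entropy([0.5, 0.5, 0, 0], UNIFORM) == 1.0

    def test_posterior_mean_within_credible_interval(self):
        st = column_relative_entropy_ci([12, 1, 0, 2], seed=3)
        assert 0 <= st.ci_low <= st.mean_relative_entropy <= st.ci_high <= 2.0

    def test_ci_width_shrinks_with_counts(self):
        widths = []
        for total in (10, 100, 1000, 10000):
            counts = np.array([0.7, 0.1, 0.1, 0.1]) * total
            st = column_relative_entropy_ci(counts.astype(int), seed=4)
            widths.append(st.ci_high - st.ci_low)
        assert widths == sorted(widths, reverse=True)

    def test_zero_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            column_relative_entropy_ci([0, 0, 0, 0])


class TestScanConsensus:
    def test_each_published_14mer_contains_the_consensus(self):
        for seq in MOTIF1_14MERS:
            hits = scan_consensus([("r", seq)], "CGGA")
            assert [(h.offset, h.strand) for h in hits] == [(4, "+")]

    def test_reverse_complement_needs_both_strands(self):
        seq = "AAATCCGAAA"  # contains TCCG = revcomp(CGGA)
        assert scan_consensus([("s", seq)], "CGGA") == []
        hits = scan_consensus([("s", seq)], "CGGA", both_strands=True)
        assert [(h.offset, h.strand) for h in hits] == [(3, "-")]

    def test_iupac_degeneracy(self):
        hits = scan_consensus([("s", "ACGTACAT")], "RYGT")
        assert [h.offset for h in hits] == [0]

    def test_overlapping_matches_reported(self):
        hits = scan_consensus([("s", "AAAA")], "AA")
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_invalid_code_rejected(self):
        with pytest.raises(SequenceError):
            scan_consensus([("s", "ACGT")], "CGZ")

    def test_hits_invariant_under_global_reverse_complement(self):
        rng = np.random.default_rng(31)
        seqs = [("s%d" % i, "".join(rng.choice(list("ACGT"), 80)))
                for i in range(20)]
        fwd = scan_consensus(seqs, "CGGA", both_strands=True)
        rc = scan_consensus([(i, revcomp(s)) for i, s in seqs], "CGGA",
                            both_strands=True)
        flip = {"+": "-", "-": "+"}
        mapped = {(i, 80 - 4 - off, flip[st])
                  for i, off, st in ((h.sequence_id, h.offset, h.strand)
                                     for h in rc)}
        assert {(h.sequence_id, h.offset, h.strand) for h in fwd} == mapped


class TestGibbsSampler:
    def test_exact_plant_recovers_all_sites(self):
        seqs, offsets, _ = plant_motif_sequences(10, 200, "TTCGGAAT", 0.0,
                                                 seed=7)
        model = gibbs_motif_sampler(seqs, 8, seed=7)
        assert [s.offset for s in model.sites] == offsets
        assert model.consensus == "TTCGGAAT"

    def test_deterministic_given_seed(self):
        for seed in (0, 99):
            seqs, _, _ = plant_motif_sequences(8, 120, "TTCGGAAT", 0.1,
                                               seed=seed)
            m1 = gibbs_motif_sampler(seqs, 8, n_iterations=50, n_restarts=2,
                                     seed=seed)
            m2 = gibbs_motif_sampler(seqs, 8, n_iterations=50, n_restarts=2,
                                     seed=seed)
            assert np.array_equal(m1.pwm, m2.pwm)
            assert m1.sites == m2.sites

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ConfigurationError):
            gibbs_motif_sampler(["ACGTACGT"], 4)

    def test_width_longer_than_shortest_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            gibbs_motif_sampler(["ACGTACGT", "ACG"], 4)

    def test_both_strand_plant_recovered_up_to_orientation(self):
        seqs, offsets, strands = plant_motif_sequences(
            12, 150, "TTCGGAAT", 0.0, seed=5, both_strands=True)
        model = gibbs_motif_sampler(seqs, 8, seed=5, both_strands=True)
        assert model.consensus in ("TTCGGAAT", revcomp("TTCGGAAT"))
        found = sorted((s.offset, s.strand) for s in model.sites)
        planted = sorted(zip(offsets, strands))
        flip = {"+": "-", "-": "+"}
        flipped = sorted((o, flip[s]) for o, s in planted)
        assert found in (planted, flipped)

    def test_get_set_params(self):
        s = GibbsMotifSampler(8, seed=1)
        assert s.get_params()["width"] == 8
        s.set_params(n_restarts=3)
        assert s.n_restarts == 3
        with pytest.raises(ConfigurationError):
            s.set_params(bogus=1)


class TestPlantMotifSequences:
    def test_zero_mutation_rate_plants_exact_copies(self):
        seqs, offsets, _ = plant_motif_sequences(50, 60, "TTCGGAAT", 0.0,
                                                 seed=2)
        for s, off in zip(seqs, offsets):
            assert s[off:off + 8] == "TTCGGAAT"

    def test_deterministic(self):
        a = plant_motif_sequences(5, 50, "CGGA", 0.2, seed=9)
        b = plant_motif_sequences(5, 50, "CGGA", 0.2, seed=9)
        assert a == b

    def test_mutation_rate_matches_binomial_mean(self):
        seqs, offsets, _ = plant_motif_sequences(1000, 30, "TTCGGAAT", 0.1,
                                                 seed=13)
        mismatches = [sum(a != b for a, b in zip(s[o:o + 8], "TTCGGAAT"))
                      for s, o in zip(seqs, offsets)]
        assert np.mean(mismatches) == pytest.approx(0.8, abs=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            plant_motif_sequences(3, 4, "TTCGGAAT", 0.1, seed=1)
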