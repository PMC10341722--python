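import numpy as np
import pytest

from divrep.encoding import EncodedSequence, decode_sequence, reverse_complement
from divrep.simulate import (
    SimConfig,
    make_master,
    make_test_genome,
    mutate_copy,
    shuffle_codons,
    shuffle_noncoding,
)
from conftest import make_rng


class TestMakeMaster:
    def test_length_and_alphabet(self):
        m = make_master(600, make_rng(0))
        assert len(m) == 600
        assert set(np.unique(m.codes)) <= {1, 2, 3, 4}

    def test_base_frequencies_uniform(self):
        m = make_master(100_000, make_rng(1))
        counts = np.bincount(m.codes, minlength=5)[1:]
        # binomial 3-sigma band around 0.25
        sd = np.sqrt(100_000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 25_000) < 3 * sd)

    def test_seeded(self):
        assert np.array_equal(make_master(50, make_rng(2)).codes,
                              make_master(50, make_rng(2)).codes)


class TestMutateCopy:
    def test_zero_divergence_only_indels(self):
        master = make_master(600, make_rng(3))
        copy, log = mutate_copy(master, 0.0, 2, make_rng(4))
        assert log["n_substitution_events"] == 0
        assert len(log["indels"]) == 2
        assert abs(len(copy) - 600) <= 2

    def test_event_count_contract(self):
        master = make_master(600, make_rng(5))
        _, log = mutate_copy(master, 1.0, 2, make_rng(6))
        assert log["n_substitution_events"] == 300
        _, log = mutate_copy(master, 2.5, 0, make_rng(7))
        assert log["n_substitution_events"] == 750

    def test_substitution_never_copies_same_base(self):
        master = make_master(400, make_rng(8))
        copy, _ = mutate_copy(master, 0.3, 0, make_rng(9))
        # without indels, every differing site changed base; with 60 events
        # and multiple hits possible, differences are <= events but > 0
        diff = np.sum(copy.codes != master.codes)
        assert 0 < diff <= 60

    def test_observed_divergence_saturates_below_event_count(self):
        """Per-site observed difference stays below the event rate because
        events can hit one site repeatedly."""
        master = make_master(600, make_rng(10))
        rng = make_rng(11)
        diffs = []
        for _ in range(200):
            copy, _ = mutate_copy(master, 0.5, 0, rng)
            diffs.append(np.mean(copy.codes != master.codes))
        # 150 events over 600 sites: expected observed difference is
        # 1 - (identity under the event model), strictly below 0.25
        assert 0.15 < np.mean(diffs) < 0.25

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            mutate_copy(make_master(10, make_rng(0)), -1.0, 0, make_rng(0))


class TestMakeTestGenome:
    CFG = SimConfig(genome_length=50_000, repeat_length=300, n_copies=20,
                    x=0.5, frac_reverse=0.5, seed=77)

    def test_counts_and_orientations(self):
        genome, truth = make_test_genome(self.CFG)
        assert len(truth.copies) == 20
        assert sum(c.reverse for c in truth.copies) == 10

    def test_length_conservation(self):
        genome, truth = make_test_genome(self.CFG)
        inserted = sum(len(c.sequence) for c in truth.copies)
        assert len(genome) == self.CFG.genome_length + inserted

    def test_truth_intervals_disjoint_and_in_range(self):
        genome, truth = make_test_genome(self.CFG)
        iv = truth.intervals()
        assert np.all(iv[:, 0] >= 1) and np.all(iv[:, 1] <= len(genome))
        assert np.all(iv[1:, 0] > iv[:-1, 1])

    def test_planted_sequences_verbatim(self):
        genome, truth = make_test_genome(self.CFG)
        for c in truth.copies:
            assert np.array_equal(genome.codes[c.start - 1 : c.end], c.sequence.codes)

    def test_reverse_copies_are_reverse_complements(self):
        genome, truth = make_test_genome(SimConfig(
            genome_length=30_000, repeat_length=200, n_copies=10,
            x=0.0, n_indels=0, frac_reverse=1.0, seed=5))
        for c in truth.copies:
            assert np.array_equal(
                reverse_complement(c.sequence).codes, truth.master.codes
            )

    def test_seed_determinism(self):
        a, _ = make_test_genome(self.CFG)
        b, _ = make_test_genome(self.CFG)
        assert np.array_equal(a.codes, b.codes)

    def test_overfull_genome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=1000, repeat_length=600, n_copies=5)


class TestShuffleCodons:
    def test_single_codon_gene_unchanged(self):
        genome = EncodedSequence(np.array([1, 2, 3, 4, 1, 2], np.int8))
        out = shuffle_codons(genome, [(2, 4)], make_rng(0))
        assert np.array_equal(out.codes, genome.codes)

    def test_codon_multiset_preserved(self):
        rng = make_rng(1)
        genome = EncodedSequence(rng.integers(1, 5, 300).astype(np.int8))
        out = shuffle_codons(genome, [(1, 300)], make_rng(2))
        before = genome.codes.reshape(-1, 3)
        after = out.codes.reshape(-1, 3)
        assert sorted(map(tuple, before)) == sorted(map(tuple, after))

    def test_frame_composition_preserved(self):
        """Base composition at each codon position of a gene is unchanged."""
        rng = make_rng(3)
        genome = EncodedSequence(rng.integers(1, 5, 600).astype(np.int8))
        out = shuffle_codons(genome, [(101, 400)], make_rng(4))
        b = genome.codes[100:400].reshape(-1, 3)
        a = out.codes[100:400].reshape(-1, 3)
        for frame in range(3):
            assert np.array_equal(np.bincount(b[:, frame], minlength=5),
                                  np.bincount(a[:, frame], minlength=5))
        assert np.array_equal(out.codes[:100], genome.codes[:100])
        assert np.array_equal(out.codes[400:], genome.codes[400:])

    def test_non_multiple_of_three_skipped(self):
        rng = make_rng(5)
        genome = EncodedSequence(rng.integers(1, 5, 100).astype(np.int8))
        out = shuffle_codons(genome, [(1, 50)], make_rng(6))
        assert np.array_equal(out.codes, genome.codes)


class TestShuffleNoncoding:
    def test_fully_coding_unchanged(self):
        rng = make_rng(7)
        genome = EncodedSequence(rng.integers(1, 5, 90).astype(np.int8))
        out = shuffle_noncoding(genome, [(1, 90)], make_rng(8))
        assert np.array_equal(out.codes, genome.codes)

    def test_cds_untouched_and_counts_preserved(self):
        rng = make_rng(9)
        genome = EncodedSequence(rng.integers(1, 5, 500).astype(np.int8))
        cds = [(101, 200), (301, 340)]
        out = shuffle_noncoding(genome, cds, make_rng(10))
        for s, e in cds:
            assert np.array_equal(out.codes[s - 1 : e], genome.codes[s - 1 : e])
        mask = np.ones(500, bool)
        for s, e in cds:
            mask[s - 1 : e] = False
        assert np.array_equal(np.bincount(out.codes[mask], minlength=5),
                              np.bincount(genome.codes[mask], minlength=5))
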