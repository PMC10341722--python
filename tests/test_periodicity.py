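import numpy as np
import pytest

from divrep.periodicity import (
    PhaseMatrix,
    family_phase_z,
    mutual_information,
    phase_function,
    phase_matrix,
)
from oracle import oracle_mutual_information

SQRT11 = np.sqrt(11.0)


class TestPhaseFunction:
    @pytest.mark.parametrize("col,phase", [(1, 1), (2, 2), (3, 3), (4, 1),
                                           (5, 2), (6, 3), (600, 3)])
    def test_printed_formula_values(self, col, phase):
        assert phase_function(col) == phase

    def test_period_three(self):
        for col in range(1, 200):
            assert phase_function(col + 3) == phase_function(col)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            phase_function(0)


class TestPhaseMatrix:
    def test_all_gap_input_is_empty(self):
        m = phase_matrix(np.zeros(5, int), np.zeros(5, int))
        assert m.total == 0

    def test_ungapped_nine_positions(self):
        s1 = np.array([1, 2, 3, 4, 1, 2, 3, 4, 1])
        s2 = np.arange(1, 10)
        m = phase_matrix(s1, s2)
        assert m.total == 9
        assert np.array_equal(m.phase_margin, [3, 3, 3])

    def test_hand_tallied_example(self):
        # positions: (col 1, A), (col 2, T), gap-in-seq, (col 4, C),
        # (gap-in-matrix base G), (col 5, G)
        s1 = np.array([1, 2, 0, 3, 4, 4])
        s2 = np.array([1, 2, 3, 4, 0, 5])
        m = phase_matrix(s1, s2)
        want = np.zeros((3, 4))
        want[0, 0] = 1  # col 1 -> phase 1, A
        want[1, 1] = 1  # col 2 -> phase 2, T
        want[0, 2] = 1  # col 4 -> phase 1, C
        want[1, 3] = 1  # col 5 -> phase 2, G
        assert np.array_equal(m.counts, want)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            phase_matrix(np.ones(3, int), np.ones(4, int))


class TestMutualInformation:
    def test_independent_margins_give_zero(self):
        # outer product of margins: counts m = X Y / L exactly
        m = np.outer([12, 24, 12], [6, 12, 18, 12]) / 48.0
        res = mutual_information(PhaseMatrix(m))
        assert res.mutual_information == 0.0
        assert res.z == pytest.approx(-SQRT11, abs=1e-12)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = rng.integers(0, 30, size=(3, 4)).astype(float)
            if m.sum() < 1:
                continue
            res = mutual_information(PhaseMatrix(m))
            assert res.mutual_information == pytest.approx(
                max(oracle_mutual_information(m), 0.0), abs=1e-12)

    def test_diagonal_matrix_value(self):
        m = np.array([[3.0, 0, 0, 0], [0, 3.0, 0, 0], [0, 0, 3.0, 0]])
        res = mutual_information(PhaseMatrix(m))
        # 9 ln 9 - 3*(3 ln 3) - 3*(3 ln 3) + ... by direct Eq evaluation
        assert res.mutual_information == pytest.approx(
            oracle_mutual_information(m), abs=1e-12)
        assert res.mutual_information == pytest.approx(9 * np.log(3.0), abs=1e-9)

    def test_nonnegative_on_random_counts(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            m = rng.integers(0, 10, size=(3, 4)).astype(float)
            if m.sum() < 1:
                continue
            assert mutual_information(PhaseMatrix(m)).mutual_information >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(PhaseMatrix(np.zeros((3, 4))))


class TestFamilyPhaseZ:
    def test_independent_combined_matrix_near_zero(self):
        m = PhaseMatrix(np.outer([10, 20, 10], [5, 10, 15, 10]) / 40.0)
        z = family_phase_z([m])
        assert z.shape == (4, 3)
        assert np.nanmax(np.abs(z)) < 1e-9

    def test_dominant_cell_pattern(self):
        base = np.full((3, 4), 5.0)
        base[0, 2] = 60.0  # phase 1, base C dominates
        z = family_phase_z([PhaseMatrix(base)])
        assert z[2, 0] > 2.0          # C at phase 1 enriched
        assert z[2, 1] < 0 and z[2, 2] < 0   # C depleted at other phases
        assert z[0, 0] < 0 and z[1, 0] < 0   # other bases depleted at phase 1

    def test_single_matrix_equals_direct_formula(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 30, size=(3, 4)).astype(float)
        z = family_phase_z([PhaseMatrix(counts)])
        L = counts.sum()
        X = counts.sum(axis=1)
        Y = counts.sum(axis=0)
        for i in range(3):
            for j in range(4):
                p = X[i] * Y[j] / L**2
                want = (counts[i, j] - L * p) / np.sqrt(L * p * (1 - p))
                assert z[j, i] == pytest.approx(want, abs=1e-12)

    def test_combination_sums_counts(self):
        a = PhaseMatrix(np.full((3, 4), 2.0))
        b = PhaseMatrix(np.full((3, 4), 3.0))
        assert np.nanmax(np.abs(family_phase_z([a, b]))) < 1e-9

    def test_degenerate_margin_reported_nan(self):
        m = np.zeros((3, 4))
        m[0, 0] = 7
        z = family_phase_z([PhaseMatrix(m)])
        assert np.isnan(z[1, 0])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            family_phase_z([])


class TestAlignedVersusUnalignedPeriodicity:
    def test_alignment_sharpens_triplet_signal(self, uniform_comp):
        """For a planted family built on a phase-patterned master, the
        alignment-aware statistic exceeds the sequential-phase statistic,
        which in turn exceeds shuffled members."""
        from divrep.periodicity import member_periodicity
        from divrep.pwm import matrix_from_sequence
        from divrep.scan import estimate_background, find_hits, scan, shuffle_sequence
        from divrep.simulate import mutate_copy
        from divrep.encoding import CompositionModel, EncodedSequence

        rng = np.random.default_rng(99)
        # periodic master: phase-dependent base preference
        probs = np.array([
            [0.55, 0.15, 0.15, 0.15],   # phase 1 favors A
            [0.15, 0.15, 0.55, 0.15],   # phase 2 favors C
            [0.15, 0.55, 0.15, 0.15],   # phase 3 favors T
        ])
        codes = np.array([
            rng.choice([1, 2, 3, 4], p=probs[i % 3]) for i in range(600)
        ], dtype=np.int8)
        master = EncodedSequence(codes)
        # genome with 40 evenly spaced divergent copies of the periodic master
        host = np.random.default_rng(42).integers(1, 5, 150_000).astype(np.int8)
        step_gap = 150_000 // 41
        pos = 0
        genome_codes = []
        for _ in range(40):
            genome_codes.append(host[pos : pos + step_gap - 600])
            copy, _ = mutate_copy(master, 1.0, 2, rng)
            genome_codes.append(copy.codes)
            pos += step_gap - 600
        genome_codes.append(host[pos:])
        genome = EncodedSequence(np.concatenate(genome_codes))

        comp = CompositionModel.from_sequence(genome)
        W = matrix_from_sequence(master, comp)
        bg = estimate_background(shuffle_sequence(genome, rng), W,
                                 step=30, max_windows=800)
        profile = scan(genome, W, step=30)
        hits, n_lm, _ = find_hits(profile, bg, 5.0, S=genome, W=W)
        assert n_lm >= 30
        aligned = [r.z for r in member_periodicity(hits)]
        unaligned = [r.z for r in member_periodicity(hits, unaligned=True)]
        # shuffled members lose the signal entirely
        shuffled = []
        for h in hits:
            s1 = h.alignment.aligned_seq
            bases = rng.permutation(s1[s1 > 0])
            shuffled.append(mutual_information(
                phase_matrix(bases, np.arange(1, bases.size + 1))).z)
        assert np.mean(aligned) > np.mean(unaligned)
        assert np.mean(unaligned) > np.mean(shuffled)
        assert np.mean(aligned) > 3.0
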