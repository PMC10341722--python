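"""Shared fixtures.

Heavy pipeline runs (genome-scale scans, iterative-procedure searches) are
session-scoped so that several tests can assert different properties of one
run.  Problem sizes follow the desk-scale conventions described in
docs/methods.md: planted-repeat density is kept at the benchmark's 15%
(copies x 600 / genome length) while genome lengths, restart counts and
scan steps are reduced.
"""

from __future__ import annotations

import numpy as np
import pytest

from divrep.encoding import CompositionModel, EncodedSequence
from divrep.iterate import IPConfig, find_families
from divrep.simulate import SimConfig, make_test_genome


@pytest.fixture(scope="session")
def uniform_comp() -> CompositionModel:
    return CompositionModel.uniform()


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@pytest.fixture()
def rng() -> np.random.Generator:
    return make_rng(12345)


def random_sequence(length: int, seed: int) -> EncodedSequence:
    return EncodedSequence(make_rng(seed).integers(1, 5, length).astype(np.int8))


# --- desk-scale study configurations -------------------------------------

#: seeded single-cycle benchmark: half the printed genome/copy numbers,
#: density unchanged
BENCH_SIM = dict(genome_length=200_000, repeat_length=600, n_copies=50)
BENCH_IP = dict(L1=600, step=20, background_windows=1500, n_families=1)
BENCH_X_GRID = (0.5, 1.0, 1.5, 2.5, 4.0, 20.0)

#: blind iterative-procedure run: single-orientation takeover (100 copies)
BLIND_SIM = dict(genome_length=400_000, repeat_length=600, n_copies=100, seed=11)
BLIND_IP = dict(
    L1=600, step=20, background_windows=1500, inner_iters=6,
    restarts=2, early_stop_patience=2, n_families=1,
)

#: blind iterative-procedure runs (two-orientation recovery)
TWO_FAMILY_SIM = dict(
    genome_length=400_000, repeat_length=600, n_copies=100, frac_reverse=0.5, seed=21
)
TWO_FAMILY_IP = dict(
    L1=600, step=30, background_windows=800, inner_iters=3,
    restarts=1, early_stop_patience=1, n_families=2,
)

#: small null-run config for the noise calibration checks
NULL_IP = dict(
    L1=600, step=20, background_windows=800, inner_iters=4,
    restarts=2, early_stop_patience=1, n_families=1,
)
NULL_LENGTH = 60_000


@pytest.fixture(scope="session")
def seeded_benchmark_rows():
    """Seeded single-cycle recovery over the divergence grid."""
    from divrep.evaluate import run_benchmark

    sim = SimConfig(**BENCH_SIM, x=0.0)
    ip = IPConfig(**BENCH_IP)
    return run_benchmark(BENCH_X_GRID, sim, ip, mode="seeded_single_cycle", rng=1)


@pytest.fixture(scope="session")
def blind_recovery_run():
    """Blind IP on a genome with 100 forward planted copies at x = 1.0."""
    sim = SimConfig(**BLIND_SIM, x=1.0)
    genome, truth = make_test_genome(sim)
    cfg = IPConfig(**BLIND_IP)
    families = find_families(genome, cfg, rng=3, calibrate=False)
    return genome, truth, cfg, families


@pytest.fixture(scope="session")
def two_orientation_run():
    """Blind IP on a genome with 50 forward + 50 reverse planted copies (x=1)."""
    sim = SimConfig(**TWO_FAMILY_SIM, x=1.0)
    genome, truth = make_test_genome(sim)
    cfg = IPConfig(**TWO_FAMILY_IP)
    families = find_families(genome, cfg, rng=7, calibrate=False)
    return genome, truth, cfg, families


@pytest.fixture(scope="session")
def collapse_run():
    """Blind IP at x = 2.0, where recovery is expected to collapse."""
    sim = SimConfig(
        genome_length=200_000, repeat_length=600, n_copies=50,
        frac_reverse=0.5, x=2.0, seed=22,
    )
    genome, truth = make_test_genome(sim)
    cfg = IPConfig(
        L1=600, step=30, background_windows=800, inner_iters=3,
        restarts=1, early_stop_patience=1, n_families=1,
    )
    families = find_families(genome, cfg, rng=9, calibrate=False)
    return genome, truth, cfg, families


@pytest.fixture(scope="session")
def null_runs():
    """Family sizes found on pure random sequences across seeds."""
    cfg = IPConfig(**NULL_IP)
    sizes = []
    for seed in (101, 102, 103):
        S = random_sequence(NULL_LENGTH, seed)
        fams = find_families(S, cfg, rng=seed, calibrate=False)
        sizes.append(fams[0].n_members)
    return cfg, sizes


def overlap_count(hits, intervals, min_overlap=0.5):
    """Hits covering >= min_overlap of some interval (each hit counted once)."""
    n = 0
    for h in hits:
        for s, e in intervals:
            ov = min(h.genome_end, e) - max(h.genome_start, s) + 1
            if ov > 0 and ov / (e - s + 1) >= min_overlap:
                n += 1
                break
    return n
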