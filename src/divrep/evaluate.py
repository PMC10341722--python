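"""Benchmark harness and the analytic detectability threshold.

``detectability`` reproduces the pairwise-comparison noise threshold: over a
sequence of length L there are about N = L^2/2 window pairs, so a pairwise
similarity is trustworthy only if its random probability is below p = k/N;
converting p to a normal quantile z0 gives the minimal matching-base count
``s0 = L1 t + z0 sqrt(L1 t (1 - t))`` that exceeds noise.

``run_benchmark`` replays the planted-genome protocols: ``seeded_single_cycle``
builds the matrix from the known master and performs one scan (the
known-library comparison), ``full_ip`` runs the blind iterative procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from divrep.encoding import CompositionModel, EncodedSequence
from divrep.iterate import IPConfig, find_families
from divrep.pwm import matrix_from_sequence
from divrep.scan import Hit, estimate_background, find_hits, scan, shuffle_sequence
from divrep.simulate import SimConfig, SimTruth, make_test_genome


@dataclass(frozen=True)
class DetectabilityResult:
    n_comparisons: float
    p: float
    z0: float
    s_mean: float
    s0: float


def detectability(
    L: float,
    L1: float,
    k: float = 0.01,
    t: float = 0.25,
    z0_rounding: Literal["none", "integer"] = "none",
) -> DetectabilityResult:
    """Minimal number of matching bases distinguishable from noise.

    ``z0_rounding="integer"`` rounds the normal quantile to the nearest
    whole number before computing s0.
    """
    if not (L > L1 > 0):
        raise ValueError("need L > L1 > 0")
    if not (0 < t < 1 and 0 < k < 1):
        raise ValueError("k and t must be in (0, 1)")
    N = L * L / 2.0
    p = k / N
    if p >= 1:
        raise ValueError("p must be below 1")
    z0 = float(stats.norm.isf(p))
    if z0_rounding == "integer":
        z0 = float(round(z0))
    s_mean = L1 * t
    s0 = s_mean + z0 * float(np.sqrt(L1 * t * (1.0 - t)))
    return DetectabilityResult(N, p, z0, s_mean, s0)


@dataclass(frozen=True)
class BenchmarkRow:
    x: float
    n_planted: int
    n_detected: int
    sensitivity: float
    n_false: int
    n_hits: int


def sensitivity(
    hits: list[Hit],
    truth: SimTruth,
    min_overlap: float = 0.5,
) -> BenchmarkRow:
    """Score hits against planted truth.

    A planted copy is detected iff some hit covers at least ``min_overlap``
    of its interval; each hit is credited to at most one copy; hits covering
    no copy count as false.
    """
    intervals = truth.intervals()
    n_planted = intervals.shape[0]
    used = np.zeros(n_planted, dtype=bool)
    n_false = 0
    for h in hits:
        best = -1
        best_frac = 0.0
        for i in range(n_planted):
            if used[i]:
                continue
            s, e = intervals[i]
            ov = min(h.genome_end, e) - max(h.genome_start, s) + 1
            frac = ov / (e - s + 1) if ov > 0 else 0.0
            if frac > best_frac:
                best_frac = frac
                best = i
        if best >= 0 and best_frac >= min_overlap:
            used[best] = True
        else:
            n_false += 1
    n_detected = int(used.sum())
    return BenchmarkRow(
        x=truth.config.x,
        n_planted=n_planted,
        n_detected=n_detected,
        sensitivity=n_detected / n_planted if n_planted else 0.0,
        n_false=n_false,
        n_hits=len(hits),
    )


def seeded_single_cycle(
    genome: EncodedSequence,
    truth: SimTruth,
    ip_cfg: IPConfig,
    rng: np.random.Generator,
) -> list[Hit]:
    """One search cycle with the matrix seeded from the known master."""
    composition = CompositionModel.from_sequence(genome)
    W = matrix_from_sequence(truth.master, composition, K0=ip_cfg.K0, R0_sq=ip_cfg.R0_sq)
    bg = estimate_background(
        shuffle_sequence(genome, rng), W, ip_cfg.gaps,
        step=ip_cfg.step, max_windows=ip_cfg.background_windows,
    )
    profile = scan(genome, W, ip_cfg.gaps, step=ip_cfg.step)
    hits, _, _ = find_hits(profile, bg, ip_cfg.z_main, S=genome, W=W, gaps=ip_cfg.gaps)
    return hits


def run_benchmark(
    x_values: Iterable[float],
    cfg: SimConfig,
    ip_cfg: IPConfig,
    mode: Literal["full_ip", "seeded_single_cycle"] = "seeded_single_cycle",
    rng: np.random.Generator | int | None = None,
) -> list[BenchmarkRow]:
    """Planted-recovery benchmark over a grid of divergence values."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for x in x_values:
        genome, truth = make_test_genome(
            SimConfig(**{**cfg.__dict__, "x": float(x)}), rng
        )
        if mode == "seeded_single_cycle":
            hits = seeded_single_cycle(genome, truth, ip_cfg, rng)
        elif mode == "full_ip":
            families = find_families(genome, ip_cfg, rng)
            hits = [h for fam in families for h in fam.hits]
        else:
            raise ValueError(f"unknown benchmark mode {mode!r}")
        rows.append(sensitivity(hits, truth))
    return rows


def coding_fraction_report(
    families,
    cds_intervals: list[tuple[int, int]],
    genome_length: int,
    n_bins: int = 10,
) -> dict[int, np.ndarray]:
    """Histogram per family of each hit's non-coding fraction (ten 0.1 bins)."""
    coding = np.zeros(genome_length, dtype=bool)
    for start, end in cds_intervals:
        coding[max(start - 1, 0) : min(end, genome_length)] = True
    out: dict[int, np.ndarray] = {}
    for fam in families:
        hist = np.zeros(n_bins, dtype=np.int64)
        for h in fam.hits:
            span = coding[h.genome_start - 1 : h.genome_end]
            frac_noncoding = 1.0 - span.mean() if span.size else 1.0
            b = min(int(frac_noncoding * n_bins), n_bins - 1)
            hist[b] += 1
        out[fam.family_id] = hist
    return out
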