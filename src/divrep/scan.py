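"""Genome scanning: background score statistics, window profiles, hit calling.

A matrix is slid across the sequence in windows of length L1 + 50 with a
fixed step (10 by default).  The background distribution of the maximal
local-alignment score Fmax is estimated on a shuffled copy of the sequence;
hits are then the local maxima of the window profile whose standardized
score Z = (Fmax - mean) / sigma clears a threshold.  A profile position is
a local maximum only if it beats every profile position within +-(L1 + 49),
which also guarantees that accepted hits never crowd each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from divrep.align import (
    GapParams,
    LocalAlignment,
    _fill_dp,
    _fill_dp_score,
    _traceback,
    local_align,
)
from divrep.encoding import EncodedSequence

WINDOW_EXTRA = 50  # window length is L1 + 50


@dataclass(frozen=True)
class BackgroundStats:
    """Mean and sample standard deviation of Fmax over shuffled-sequence windows."""

    mean_fmax: float
    sigma: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.n_windows < 30:
            raise ValueError("background needs at least 30 windows")
        if not self.sigma > 0:
            raise ValueError("background sigma must be positive")

    def z(self, fmax: float | np.ndarray) -> float | np.ndarray:
        return (fmax - self.mean_fmax) / self.sigma


@dataclass(frozen=True)
class ScanProfile:
    """Per-window scan results: ascending window starts and alignment summaries."""

    starts: np.ndarray       # 1-based window start t
    fmax: np.ndarray
    aln_start: np.ndarray    # window-local i0 (1-based)
    aln_end: np.ndarray      # window-local imax
    L1: int

    def __post_init__(self) -> None:
        n = self.starts.size
        if not (self.fmax.size == n and self.aln_start.size == n and self.aln_end.size == n):
            raise ValueError("profile arrays must have equal length")

    def __len__(self) -> int:
        return int(self.starts.size)


@dataclass(frozen=True)
class Hit:
    """One called repeat copy: genome interval, Z score and its alignment."""

    window_start: int
    genome_start: int
    genome_end: int
    z: float
    alignment: LocalAlignment

    def __post_init__(self) -> None:
        if self.genome_start > self.genome_end:
            raise ValueError("empty hit interval")

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start + 1


def shuffle_sequence(S: EncodedSequence, rng: np.random.Generator) -> EncodedSequence:
    """Uniform random permutation of all positions (Fisher-Yates)."""
    return EncodedSequence(rng.permutation(S.codes))


@njit(cache=True, fastmath=False)
def _scan_kernel(codes, starts, wlen, weights, d, e):  # pragma: no cover - jitted
    """Run the DP over every window; return per-window score and coordinates."""
    L1 = weights.shape[1]
    nwin = starts.shape[0]
    fmax = np.zeros(nwin)
    i0 = np.zeros(nwin, dtype=np.int64)
    imax = np.zeros(nwin, dtype=np.int64)
    j0 = np.zeros(nwin, dtype=np.int64)
    jmax = np.zeros(nwin, dtype=np.int64)
    ptr = np.zeros((wlen + 1, L1 + 1), dtype=np.uint8)
    rows = np.empty((6, L1 + 1))
    nidx = np.empty(wlen, dtype=np.int64)
    s1buf = np.empty(wlen + L1, dtype=np.int64)
    s2buf = np.empty(wlen + L1, dtype=np.int64)
    for k in range(nwin):
        t0 = starts[k] - 1
        nidx[0] = codes[t0] + 4 * (codes[t0] - 1) - 1
        for i in range(1, wlen):
            nidx[i] = codes[t0 + i - 1] + 4 * (codes[t0 + i] - 1) - 1
        fm, im, jm = _fill_dp(nidx, weights, d, e, ptr, rows)
        fmax[k] = fm
        imax[k] = im
        jmax[k] = jm
        if fm > 0.0:
            _, a0, b0 = _traceback(ptr, im, jm, s1buf, s2buf)
            i0[k] = a0
            j0[k] = b0
    return fmax, i0, imax, j0, jmax


@njit(cache=True, fastmath=False)
def _scan_kernel_fast(codes, starts, wlen, weights, d, e):  # pragma: no cover - jitted
    """Score-only window sweep: per-window (fmax, imax, jmax)."""
    L1 = weights.shape[1]
    nwin = starts.shape[0]
    fmax = np.zeros(nwin)
    imax = np.zeros(nwin, dtype=np.int64)
    jmax = np.zeros(nwin, dtype=np.int64)
    rows = np.empty((6, L1 + 1))
    nidx = np.empty(wlen, dtype=np.int64)
    for k in range(nwin):
        t0 = starts[k] - 1
        nidx[0] = codes[t0] + 4 * (codes[t0] - 1) - 1
        for i in range(1, wlen):
            nidx[i] = codes[t0 + i - 1] + 4 * (codes[t0 + i] - 1) - 1
        fm, im, jm = _fill_dp_score(nidx, weights, d, e, rows)
        fmax[k] = fm
        imax[k] = im
        jmax[k] = jm
    return fmax, imax, jmax


def _valid_starts(codes: np.ndarray, wlen: int, step: int) -> np.ndarray:
    """1-based window starts t = 1, 1+step, ... whose windows are free of N."""
    L = codes.size
    if L < wlen:
        return np.empty(0, dtype=np.int64)
    starts = np.arange(1, L - wlen + 2, step, dtype=np.int64)
    bad = (codes < 1).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    n_in_window = cum[starts - 1 + wlen] - cum[starts - 1]
    return starts[n_in_window == 0]


def _run_windows(codes: np.ndarray, starts: np.ndarray, W, gaps: GapParams):
    return _scan_kernel(
        codes.astype(np.int64), starts, _window_length(W.L1),
        W.weights, gaps.open_penalty, gaps.extend_penalty,
    )


def _window_length(L1: int) -> int:
    return L1 + WINDOW_EXTRA


def estimate_background(
    S_shuffled: EncodedSequence,
    W,
    gaps: GapParams = GapParams(),
    step: int = 10,
    max_windows: int | None = 10_000,
) -> BackgroundStats:
    """Mean and sigma of Fmax over windows of a shuffled sequence.

    Ambiguous positions are dropped before windowing (a masked genome would
    otherwise leave no clean window after shuffling); if ``max_windows`` is
    set, window starts are subsampled evenly.
    """
    codes = S_shuffled.codes[S_shuffled.codes >= 1]
    wlen = _window_length(W.L1)
    if codes.size < wlen + step:
        raise ValueError("sequence too short for background estimation")
    starts = _valid_starts(codes, wlen, step)
    if max_windows is not None and starts.size > max_windows:
        idx = np.linspace(0, starts.size - 1, max_windows).round().astype(np.int64)
        starts = starts[np.unique(idx)]
    if starts.size < 30:
        raise ValueError(f"only {starts.size} usable background windows (need 30)")
    fmax, *_ = _run_windows(codes, starts, W, gaps)
    sigma = float(np.std(fmax, ddof=1))
    if sigma <= 0:
        raise ValueError("degenerate background: sigma is zero")
    return BackgroundStats(float(np.mean(fmax)), sigma, int(starts.size))


def scan(
    S: EncodedSequence,
    W,
    gaps: GapParams = GapParams(),
    step: int = 10,
) -> ScanProfile:
    """Window profile of Fmax over S; windows containing N are skipped."""
    codes = S.codes
    wlen = _window_length(W.L1)
    if codes.size < wlen + step:
        raise ValueError("sequence shorter than one window plus step")
    starts = _valid_starts(codes, wlen, step)
    if starts.size == 0:
        return ScanProfile(
            starts, np.empty(0), np.empty(0, np.int64), np.empty(0, np.int64), W.L1
        )
    fmax, i0, imax, _, _ = _run_windows(codes, starts, W, gaps)
    return ScanProfile(starts, fmax, i0, imax, W.L1)


@njit(cache=True)
def _local_maxima_mask(starts, fmax, radius):  # pragma: no cover - jitted
    """Mask of positions whose fmax beats every profile position within
    +-radius in t.  Equal values resolve leftmost-wins, but a position must
    still be a peak: at least one strictly smaller value must exist in its
    window (a constant stretch has no local maximum)."""
    n = starts.shape[0]
    keep = np.zeros(n, dtype=np.bool_)
    lo = 0
    hi = 0
    for k in range(n):
        while starts[lo] < starts[k] - radius:
            lo += 1
        while hi < n and starts[hi] <= starts[k] + radius:
            hi += 1
        ok = fmax[k] > 0.0
        has_smaller = False
        for m in range(lo, hi):
            if m == k:
                continue
            if fmax[m] > fmax[k] or (fmax[m] == fmax[k] and m < k):
                ok = False
                break
            if fmax[m] < fmax[k]:
                has_smaller = True
        keep[k] = ok and (has_smaller or hi - lo == 1)
    return keep


def _local_maxima(starts: np.ndarray, fmax: np.ndarray, radius: int) -> np.ndarray:
    if starts.size == 0:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero(_local_maxima_mask(starts, fmax, int(radius)))


def find_hits(
    profile: ScanProfile,
    bg: BackgroundStats,
    z_threshold: float,
    S: EncodedSequence | None = None,
    W=None,
    gaps: GapParams = GapParams(),
) -> tuple[list[Hit], int, float]:
    """Call hits at profile local maxima with Z >= z_threshold.

    Returns (hits, N_lm, Z_bar).  When ``S`` and ``W`` are given, each hit
    carries its full alignment (recomputed on the hit window); otherwise
    alignments are empty placeholders with the recorded coordinates.
    """
    if len(profile) == 0:
        return [], 0, float("nan")
    radius = profile.L1 + WINDOW_EXTRA - 1
    cand = _local_maxima(profile.starts, profile.fmax, radius)
    z = bg.z(profile.fmax[cand])
    cand = cand[z >= z_threshold]
    hits: list[Hit] = []
    wlen = _window_length(profile.L1)
    for k in cand:
        t = int(profile.starts[k])
        if S is not None and W is not None:
            window = EncodedSequence(S.codes[t - 1 : t - 1 + wlen])
            aln = local_align(window, W, gaps)
        else:
            empty = np.empty(0, dtype=np.int64)
            aln = LocalAlignment(
                float(profile.fmax[k]),
                int(profile.aln_start[k]), int(profile.aln_end[k]),
                0, -1, empty, empty,
            )
        hits.append(
            Hit(
                window_start=t,
                genome_start=t + aln.seq_start - 1,
                genome_end=t + aln.seq_end - 1,
                z=float(bg.z(profile.fmax[k])),
                alignment=aln,
            )
        )
    n_lm = len(hits)
    z_bar = float(np.mean([h.z for h in hits])) if hits else float("nan")
    return hits, n_lm, z_bar
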