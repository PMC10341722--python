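"""Independent brute-force oracles used by the test suite.

These recompute quantities by direct enumeration or per-cell arithmetic,
sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def oracle_local_fmax(codes: np.ndarray, weights: np.ndarray, d: float, e: float) -> float:
    """Maximal local alignment score by exhaustive path enumeration.

    A path is a sequence of matched (base, column) pairs advancing
    diagonally, with optional gap runs (penalty d + (len-1)*e) in one
    direction between consecutive matches; it starts and ends with a match.
    The dinucleotide row of position i pairs it with position i-1 (position
    1 with itself).
    """
    m = len(codes)
    L1 = weights.shape[1]
    # 1-based score lookup s[i][j]
    nrow = np.empty(m + 1, dtype=np.int64)
    for i in range(1, m + 1):
        prev = codes[i - 2] if i >= 2 else codes[0]
        nrow[i] = prev + 4 * (codes[i - 1] - 1) - 1
    best = 0.0

    def extend(i: int, j: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < m and j < L1:
            extend(i + 1, j + 1, score + weights[nrow[i + 1], j])
        # gap run consuming bases, then a match
        for a in range(1, m - i):
            if j < L1:
                extend(i + a + 1, j + 1,
                       score - (d + (a - 1) * e) + weights[nrow[i + a + 1], j])
        # gap run consuming columns, then a match
        for b in range(1, L1 - j):
            if i < m:
                extend(i + 1, j + b + 1,
                       score - (d + (b - 1) * e) + weights[nrow[i + 1], j + b])

    for i in range(1, m + 1):
        for j in range(1, L1 + 1):
            extend(i, j, weights[nrow[i], j - 1])
    return best


def oracle_normal_argument(M: np.ndarray) -> np.ndarray:
    """Per-cell standardization of a count matrix, scalar arithmetic per cell."""
    M = np.asarray(M, dtype=float)
    N = M.sum()
    out = np.zeros_like(M)
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            p = (M[i].sum() / N) * (M[:, j].sum() / N)
            if 0.0 < p < 1.0:
                out[i, j] = (M[i, j] - N * p) / np.sqrt(N * p * (1.0 - p))
    return out


def oracle_mutual_information(m: np.ndarray) -> float:
    """Direct scalar summation of the phase/base information statistic."""
    m = np.asarray(m, dtype=float)
    L = m.sum()

    def xlx(v: float) -> float:
        return v * np.log(v) if v > 0 else 0.0

    total = sum(xlx(m[i, j]) for i in range(3) for j in range(4))
    total -= sum(xlx(m[i, :].sum()) for i in range(3))
    total -= sum(xlx(m[:, j].sum()) for j in range(4))
    total += xlx(L)
    return total


def oracle_interval_detected(hit_ivs, truth_iv, min_overlap=0.5) -> bool:
    """Per-base overlap check for one truth interval against hit intervals."""
    s, e = truth_iv
    length = e - s + 1
    for hs, he in hit_ivs:
        covered = sum(1 for p in range(s, e + 1) if hs <= p <= he)
        if covered / length >= min_overlap:
            return True
    return False
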