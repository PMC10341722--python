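"""Local alignment of a weight matrix against a sequence window.

The similarity function is filled by the affine-gap recurrence

    F(i,j)  = max(0, max(F, Fx, Fy)(i-1, j-1) + w(n_i, j))
    Fx(i,j) = max(F(i-1, j) - d, Fx(i-1, j) - e)     # base i vs gap
    Fy(i,j) = max(F(i, j-1) - d, Fy(i, j-1) - e)     # column j vs gap

where ``n_i`` is the dinucleotide row of window position i — the ordered
pair (previous base, current base); position 1 pairs the first base with
itself.  A gap run in one direction cannot immediately follow one in the
other (Fx feeds only from F or Fx, Fy only from F or Fy), and every
alignment starts and ends with a matched column.  Fmax is the global
maximum of F; ties go to the smallest (i, j) in row-major order, and
traceback prefers the match predecessor, then Fx, then Fy.

The fill keeps only two rows of each score matrix (cache-resident) and a
one-byte-per-cell back-pointer matrix for the traceback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from divrep.encoding import EncodedSequence

NEG_INF = -1.0e30


@dataclass(frozen=True)
class GapParams:
    """Affine gap penalties: ``open_penalty`` to start a gap, ``extend_penalty`` per extra position."""

    open_penalty: float = 35.0
    extend_penalty: float = 3.5

    def __post_init__(self) -> None:
        if not (self.open_penalty > 0 and self.extend_penalty > 0):
            raise ValueError("gap penalties must be positive")
        if self.open_penalty < self.extend_penalty:
            raise ValueError("open penalty must be >= extend penalty")


@dataclass(frozen=True)
class LocalAlignment:
    """One PWM-vs-window local alignment.

    Coordinates are 1-based inclusive; ``seq_start``/``seq_end`` index the
    window, ``pwm_start``/``pwm_end`` the matrix columns.  ``aligned_seq``
    holds base codes with 0 where a matrix column is unmatched (gap in
    sequence); ``aligned_cols`` holds column numbers with 0 where a base is
    unmatched (gap in matrix).  An empty alignment has score 0.
    """

    score: float
    seq_start: int
    seq_end: int
    pwm_start: int
    pwm_end: int
    aligned_seq: np.ndarray
    aligned_cols: np.ndarray

    def __len__(self) -> int:
        return int(self.aligned_seq.size)


# back-pointer encoding per cell:
#   bits 0-1: F predecessor (0 = F is zero here, 1 = match, 2 = Fx, 3 = Fy)
#   bit 2:    Fx opened from F (set) or extended from Fx (clear)
#   bit 3:    Fy opened from F (set) or extended from Fy (clear)


@njit(cache=True, fastmath=False)
def _fill_dp(nidx, weights, d, e, ptr, rows):  # pragma: no cover - jitted
    """Affine-gap fill with rolling rows; returns (fmax, imax, jmax).

    ``ptr`` is the (m+1, L1+1) back-pointer matrix; ``rows`` a (6, L1+1)
    float64 workspace.  Row-major first occurrence wins ties for the argmax.
    """
    m = nidx.shape[0]
    L1 = weights.shape[1]
    Fprev = rows[0]
    Fxprev = rows[1]
    Fyprev = rows[2]
    Fcur = rows[3]
    Fxcur = rows[4]
    Fycur = rows[5]
    for j in range(L1 + 1):
        Fprev[j] = 0.0
        Fxprev[j] = NEG_INF
        Fyprev[j] = NEG_INF
    fmax = 0.0
    imax = 0
    jmax = 0
    for i in range(1, m + 1):
        n = nidx[i - 1]
        Fcur[0] = 0.0
        Fxcur[0] = NEG_INF
        Fycur[0] = NEG_INF
        fy = NEG_INF
        fleft = 0.0
        for j in range(1, L1 + 1):
            s = weights[n, j - 1]
            best = Fprev[j - 1]
            c = 1
            if Fxprev[j - 1] > best:
                best = Fxprev[j - 1]
                c = 2
            if Fyprev[j - 1] > best:
                best = Fyprev[j - 1]
                c = 3
            f = best + s
            if f <= 0.0:
                f = 0.0
                c = 0
            a = Fprev[j] - d
            b = Fxprev[j] - e
            if a >= b:
                fx = a
                c |= 4
            else:
                fx = b
            a = fleft - d
            b = fy - e
            if a >= b:
                fy = a
                c |= 8
            else:
                fy = b
            Fcur[j] = f
            Fxcur[j] = fx
            Fycur[j] = fy
            ptr[i, j] = c
            fleft = f
            if f > fmax:
                fmax = f
                imax = i
                jmax = j
        tmp = Fprev; Fprev = Fcur; Fcur = tmp
        tmp = Fxprev; Fxprev = Fxcur; Fxcur = tmp
        tmp = Fyprev; Fyprev = Fycur; Fycur = tmp
    return fmax, imax, jmax


@njit(cache=True, fastmath=False)
def _traceback(ptr, imax, jmax, s1_out, s2_out):  # pragma: no cover - jitted
    """Walk back-pointers from the argmax to the alignment origin.

    Writes (window index | 0) and (column | 0) pairs in reverse order and
    returns (length, i0, j0).  State 0 = match, 1 = gap in columns,
    2 = gap in sequence.
    """
    pos = 0
    i = imax
    j = jmax
    state = 0
    while i > 0 and j > 0:
        c = ptr[i, j]
        if state == 0:
            pc = c & 3
            if pc == 0:
                break
            s1_out[pos] = i
            s2_out[pos] = j
            pos += 1
            i -= 1
            j -= 1
            if pc == 1:
                if i == 0 or j == 0 or (ptr[i, j] & 3) == 0:
                    break  # predecessor has F = 0: origin found
            elif pc == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            s1_out[pos] = i
            s2_out[pos] = 0
            pos += 1
            opened = (c & 4) != 0
            i -= 1
            if opened:
                state = 0
        else:
            s1_out[pos] = 0
            s2_out[pos] = j
            pos += 1
            opened = (c & 8) != 0
            j -= 1
            if opened:
                state = 0
    return pos, i + 1, j + 1


@njit(cache=True, fastmath=False)
def _fill_dp_score(nidx, weights, d, e, rows):  # pragma: no cover - jitted
    """Score-only fill (no traceback): returns (fmax, imax, jmax).

    Equivalent to :func:`_fill_dp`; F and Fx depend only on the previous
    row, so they are computed in branch-free vectorizable sweeps, leaving
    only the short Fy running chain serial.
    """
    m = nidx.shape[0]
    L1 = weights.shape[1]
    Fprev = rows[0]
    Fxprev = rows[1]
    Fyprev = rows[2]
    Fcur = rows[3]
    Fxcur = rows[4]
    Fycur = rows[5]
    for j in range(L1 + 1):
        Fprev[j] = 0.0
        Fxprev[j] = NEG_INF
        Fyprev[j] = NEG_INF
    fmax = 0.0
    imax = 0
    jmax = 0
    for i in range(1, m + 1):
        w = weights[nidx[i - 1]]
        Fcur[0] = 0.0
        Fxcur[0] = NEG_INF
        Fycur[0] = NEG_INF
        for j in range(1, L1 + 1):
            best = max(Fprev[j - 1], Fxprev[j - 1], Fyprev[j - 1]) + w[j - 1]
            Fcur[j] = best if best > 0.0 else 0.0
        for j in range(1, L1 + 1):
            Fxcur[j] = max(Fprev[j] - d, Fxprev[j] - e)
        fy = NEG_INF
        for j in range(1, L1 + 1):
            fy = max(Fcur[j - 1] - d, fy - e)
            Fycur[j] = fy
        rbest = 0.0
        rarg = 0
        for j in range(1, L1 + 1):
            if Fcur[j] > rbest:
                rbest = Fcur[j]
                rarg = j
        if rbest > fmax:
            fmax = rbest
            imax = i
            jmax = rarg
        tmp = Fprev; Fprev = Fcur; Fcur = tmp
        tmp = Fxprev; Fxprev = Fxcur; Fxcur = tmp
        tmp = Fyprev; Fyprev = Fycur; Fycur = tmp
    return fmax, imax, jmax


def _window_nidx(codes: np.ndarray) -> np.ndarray:
    prev = np.empty_like(codes)
    prev[0] = codes[0]
    prev[1:] = codes[:-1]
    return (prev + 4 * (codes - 1) - 1).astype(np.int64)


def local_align(window: EncodedSequence, W, gaps: GapParams = GapParams()) -> LocalAlignment:
    """Optimal local alignment between ``W`` and ``window`` (see module docs)."""
    codes = window.codes.astype(np.int64)
    if codes.size == 0:
        raise ValueError("empty window")
    if np.any(codes < 1):
        raise ValueError("window contains gap or ambiguity codes")
    nidx = _window_nidx(codes)
    weights = W.weights
    m = codes.size
    L1 = weights.shape[1]
    ptr = np.zeros((m + 1, L1 + 1), dtype=np.uint8)
    rows = np.empty((6, L1 + 1))
    fmax, imax, jmax = _fill_dp(nidx, weights, gaps.open_penalty, gaps.extend_penalty, ptr, rows)
    if fmax <= 0.0:
        empty = np.empty(0, dtype=np.int64)
        return LocalAlignment(0.0, 0, -1, 0, -1, empty, empty)
    s1_rev = np.empty(m + L1, dtype=np.int64)
    s2_rev = np.empty(m + L1, dtype=np.int64)
    length, i0, j0 = _traceback(ptr, imax, jmax, s1_rev, s2_rev)
    s1 = s1_rev[:length][::-1].copy()
    s2 = s2_rev[:length][::-1].copy()
    # replace window indices by base codes (0 stays a gap)
    bases = np.where(s1 > 0, codes[np.maximum(s1 - 1, 0)], 0)
    return LocalAlignment(
        score=float(fmax),
        seq_start=int(i0),
        seq_end=int(imax),
        pwm_start=int(j0),
        pwm_end=int(jmax),
        aligned_seq=bases.astype(np.int64),
        aligned_cols=s2,
    )
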