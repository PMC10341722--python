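"""Triplet periodicity of repeat members via phase-count mutual information.

Each aligned position of a repeat contributes one count to a 3 x 4 matrix
indexed by (codon-like phase of its matrix column, base identity); gap
positions contribute nothing.  The statistic

    I = sum_ij m ln m - sum_i X ln X - sum_j Y ln Y + L ln L

(natural logs, 0 ln 0 = 0, margins X and Y, total L) is L times the mutual
information between phase and base, and is mapped to a normal argument
``z = sqrt(4 I) - sqrt(11)``.  Family-level structure is read from the
cell-wise standardized deviations of the summed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PhaseMatrix:
    """3 phases x 4 bases count matrix with its margins."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=np.float64)
        if m.shape != (3, 4):
            raise ValueError("phase matrix must be 3 x 4")
        if np.any(m < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", m)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def phase_margin(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def base_margin(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class TPResult:
    mutual_information: float
    z: float


def phase_function(col: int) -> int:
    """Phase 1..3 of matrix column ``col``: col - 3*int((col - 0.1)/3)."""
    if col <= 0:
        raise ValueError("column numbers start at 1")
    return col - 3 * int((col - 0.1) / 3.0)


def phase_matrix(aligned_seq: np.ndarray, aligned_cols: np.ndarray) -> PhaseMatrix:
    """Tally (phase of column, base) over non-gap aligned positions."""
    s1 = np.asarray(aligned_seq, dtype=np.int64)
    s2 = np.asarray(aligned_cols, dtype=np.int64)
    if s1.size != s2.size:
        raise ValueError("aligned sequences must have equal length")
    m = np.zeros((3, 4), dtype=np.float64)
    for base, col in zip(s1, s2):
        if base > 0 and col > 0:
            m[phase_function(int(col)) - 1, base - 1] += 1.0
    return PhaseMatrix(m)


def _xlogx(v) -> np.ndarray:
    v = np.atleast_1d(np.asarray(v, dtype=np.float64))
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = v[pos] * np.log(v[pos])
    return out


def mutual_information(M: PhaseMatrix) -> TPResult:
    """I (in count-weighted nats) and its normal argument z = sqrt(4I) - sqrt(11)."""
    L = M.total
    if L < 1:
        raise ValueError("empty phase matrix")
    I = float(
        _xlogx(M.counts).sum()
        - _xlogx(M.phase_margin).sum()
        - _xlogx(M.base_margin).sum()
        + float(_xlogx(L).sum())
    )
    if I < 1e-12:  # clip the floating residue of exact independence
        I = 0.0
    return TPResult(I, float(np.sqrt(4.0 * I) - np.sqrt(11.0)))


def family_phase_z(matrices: list[PhaseMatrix]) -> np.ndarray:
    """Cell-wise normal arguments of the family-combined phase matrix.

    Matrices are summed; with margins X, Y and total L, each cell becomes
    ``(m - L p) / sqrt(L p (1 - p))`` with ``p = X Y / L^2``.  The result is
    arranged 4 bases (A, T, C, G) x 3 phases; cells whose p degenerates to
    0 or 1 are reported as NaN.
    """
    if not matrices:
        raise ValueError("need at least one phase matrix")
    combined = np.sum([m.counts for m in matrices], axis=0)
    L = combined.sum()
    X = combined.sum(axis=1, keepdims=True)
    Y = combined.sum(axis=0, keepdims=True)
    p = (X / L) * (Y / L)
    z = np.full_like(combined, np.nan)
    ok = (p > 0.0) & (p < 1.0)
    z[ok] = (combined[ok] - L * p[ok]) / np.sqrt(L * p[ok] * (1.0 - p[ok]))
    return z.T  # bases x phases


def member_periodicity(hits, unaligned: bool = False) -> list[TPResult]:
    """Per-member triplet periodicity for a list of hits.

    ``unaligned=True`` ignores the alignment and phases the member's bases
    sequentially 1, 2, 3, ... as they occur in the genome.
    """
    out = []
    for h in hits:
        s1 = h.alignment.aligned_seq
        if unaligned:
            bases = s1[s1 > 0]
            cols = np.arange(1, bases.size + 1)
            out.append(mutual_information(phase_matrix(bases, cols)))
        else:
            out.append(mutual_information(phase_matrix(s1, h.alignment.aligned_cols)))
    return out
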