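"""Position-weight matrices over dinucleotide context and their normalization.

Every matrix used for alignment satisfies two constraints:

* ``R^2 = sum_ij w(i,j)^2 = R0_sq`` — fixed total squared norm;
* ``K = sum_j sum_i w(i,j) p1(i) = K0`` — fixed expected score of a full
  gap-free alignment under the background, with ``p1`` the dinucleotide
  prior of the analyzed sequence.

``K0 = -1`` makes the expected total background score of an aligned
matrix slightly negative — a drift of -1/L1 per column — which anchors the
start and end of local alignments without truncating the weak, extended
similarities the method lives on; the norm constraint ``R0_sq =
300 * sqrt(L1)`` fixes the score scale (cell rms about 0.9 at L1 = 600) so
that one set of gap penalties works for every matrix: opening a gap
(d = 35) costs about forty typical column scores, so gaps appear only
where the sequence demands them.

Normalization applies the affine map ``w' = a*w + b`` — the unique
two-parameter family that preserves the relative structure of the matrix —
with (a, b) solved in closed form so both constraints hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import numpy as np

from divrep.encoding import CompositionModel, EncodedSequence, dinucleotide_index


def default_r0_sq(L1: int) -> float:
    return 300.0 * float(np.sqrt(L1))


@dataclass(frozen=True)
class WeightMatrix:
    """A normalized 16 x L1 weight matrix with its normalization constants."""

    weights: np.ndarray
    K0: float
    R0_sq: float
    composition: CompositionModel

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != 16:
            raise ValueError("weights must be a 16 x L1 array")
        object.__setattr__(self, "weights", w)

    @property
    def L1(self) -> int:
        return int(self.weights.shape[1])

    def norm_sq(self) -> float:
        return float(np.sum(self.weights**2))

    def weighted_sum(self) -> float:
        """Expected gap-free alignment score under the background: sum over
        columns of the p1-weighted column mean."""
        return float(self.composition.p1 @ self.weights.sum(axis=1))


def normalize_matrix(
    W: np.ndarray,
    composition: CompositionModel,
    K0: float = -1.0,
    R0_sq: float | None = None,
) -> WeightMatrix:
    """Affinely rescale ``W`` so that K = K0 and R^2 = R0_sq exactly.

    A constant shift changes K by ``b * L1`` (the p1 prior sums to one in
    each column), so ``b = (K0 - a*K) / L1`` enforces the K constraint for
    any a; substituting into the norm constraint leaves a quadratic
    ``A a^2 + B a + C = 0`` whose a > 0 root is taken.  Raises if ``W`` is
    constant or no positive real root exists.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != 16:
        raise ValueError("W must be 16 x L1")
    L1 = W.shape[1]
    if R0_sq is None:
        R0_sq = default_r0_sq(L1)
    if np.ptp(W) == 0.0:
        raise ValueError("constant matrix cannot be normalized")

    p1 = composition.p1
    n_cells = 16 * L1
    K = float(p1 @ W.sum(axis=1))
    Sw = float(W.sum())
    Ssq = float(np.sum(W**2))

    # b = b0 + b1*a with:
    b0 = K0 / L1
    b1 = -K / L1
    A = Ssq + 2.0 * b1 * Sw + n_cells * b1 * b1
    B = 2.0 * b0 * Sw + 2.0 * n_cells * b0 * b1
    C = n_cells * b0 * b0 - R0_sq
    if A <= 0.0:
        raise ValueError("degenerate matrix: no scale freedom")
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        raise ValueError(
            f"constraints unsatisfiable: R0_sq={R0_sq} below the feasible floor"
        )
    a = (-B + np.sqrt(disc)) / (2.0 * A)
    if a <= 0.0:
        raise ValueError("no positive root: constraints unsatisfiable for this matrix")
    b = b0 + b1 * a
    out = a * W + b
    return WeightMatrix(out, K0=K0, R0_sq=float(R0_sq), composition=composition)


def random_matrix(
    L1: int,
    rng: np.random.Generator,
    composition: CompositionModel,
    K0: float = -1.0,
    R0_sq: float | None = None,
) -> WeightMatrix:
    """A normalized matrix with i.i.d. standard-normal raw entries."""
    if L1 < 2:
        raise ValueError("L1 must be at least 2")
    raw = rng.standard_normal((16, L1))
    return normalize_matrix(raw, composition, K0=K0, R0_sq=R0_sq)


def counts_to_normal_arguments(M: np.ndarray) -> np.ndarray:
    """Per-cell standardized deviation of counts from margin independence.

    ``p(i,j) = x(i) y(j) / N^2`` from the count margins; each cell becomes
    ``(M - N p) / sqrt(N p (1 - p))``; cells with p in {0, 1} map to 0.
    """
    M = np.asarray(M, dtype=np.float64)
    if np.any(M < 0):
        raise ValueError("counts must be nonnegative")
    N = M.sum()
    if N < 2:
        raise ValueError("need a total count of at least 2")
    x = M.sum(axis=1, keepdims=True)
    y = M.sum(axis=0, keepdims=True)
    p = (x / N) * (y / N)
    out = np.zeros_like(M)
    ok = (p > 0.0) & (p < 1.0)
    out[ok] = (M[ok] - N * p[ok]) / np.sqrt(N * p[ok] * (1.0 - p[ok]))
    return out


def matrix_from_counts(
    M: np.ndarray,
    composition: CompositionModel,
    K0: float = -1.0,
    R0_sq: float | None = None,
) -> WeightMatrix:
    """Turn a 16 x L1 frequency matrix into a normalized weight matrix.

    Counts are first standardized against margin independence
    (:func:`counts_to_normal_arguments`), then normalized.  A count matrix
    whose cells are exactly the outer product of its margins standardizes to
    the zero matrix and is rejected as a degenerate refinement.
    """
    M1 = counts_to_normal_arguments(M)
    if np.max(np.abs(M1)) < 1e-9 or np.ptp(M1) == 0.0:
        raise ValueError("degenerate counts: margins fully explain the matrix")
    return normalize_matrix(M1, composition, K0=K0, R0_sq=R0_sq)


def matrix_from_sequence(
    master: EncodedSequence,
    composition: CompositionModel,
    K0: float = -1.0,
    R0_sq: float | None = None,
) -> WeightMatrix:
    """Seed a weight matrix from a single known repeat sequence.

    Column i counts the dinucleotide (master[i-1], master[i]); column 1
    wraps around to pair the last base with the first.  The single-count
    columns are add-one smoothed (every cell +1) before the normal-argument
    transform so no margin probability degenerates.
    """
    codes = master.codes.astype(np.int64)
    L1 = codes.size
    if L1 < 2:
        raise ValueError("master must have length >= 2")
    if np.any(codes < 1):
        raise ValueError("master must be free of gap/ambiguity codes")
    M = np.zeros((16, L1), dtype=np.float64)
    for i in range(L1):
        prev = codes[i - 1]  # i == 0 wraps to the last base
        cur = codes[i]
        M[dinucleotide_index(int(prev), int(cur)) - 1, i] += 1.0
    M += 1.0
    return matrix_from_counts(M, composition, K0=K0, R0_sq=R0_sq)


# ---------------------------------------------------------------------------
# PWM text format: header "L1=<n> K0=<v> R0SQ=<v>", then 16 rows of L1 reals.

def write_pwm(W: WeightMatrix, fh: TextIO) -> None:
    fh.write(f"L1={W.L1} K0={W.K0:.12g} R0SQ={W.R0_sq:.12g}\n")
    for row in W.weights:
        fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_pwm(fh: TextIO, composition: CompositionModel | None = None) -> WeightMatrix:
    header = fh.readline().split()
    try:
        fields = dict(item.split("=", 1) for item in header)
        L1 = int(fields["L1"])
        K0 = float(fields["K0"])
        R0_sq = float(fields["R0SQ"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed PWM header: {' '.join(header)!r}") from exc
    rows = [np.array(fh.readline().split(), dtype=np.float64) for _ in range(16)]
    W = np.vstack(rows)
    if W.shape != (16, L1):
        raise ValueError("PWM body does not match header dimensions")
    if composition is None:
        composition = CompositionModel.uniform()
    return WeightMatrix(W, K0=K0, R0_sq=R0_sq, composition=composition)
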