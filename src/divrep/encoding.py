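"""Numeric sequence encoding and the dinucleotide index.

Bases are coded A=1, T=2, C=3, G=4; 0 is reserved for gap/indel positions
inside alignments and -1 marks an ambiguous base (N).  A position is scored
by the ordered pair (previous base, current base), which indexes one of the
16 rows of a weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAP = 0
AMBIG = -1

_BASE_TO_CODE = {"A": 1, "T": 2, "C": 3, "G": 4, "N": AMBIG, "-": GAP}
_CODE_TO_BASE = {1: "A", 2: "T", 3: "C", 4: "G", AMBIG: "N", GAP: "-"}

#: complement of each base code (A<->T, C<->G); index by code 1..4
_COMPLEMENT = np.array([0, 2, 1, 4, 3], dtype=np.int8)


@dataclass(frozen=True)
class EncodedSequence:
    """A DNA sequence in numeric code.

    codes: int8 array with entries in {-1, 0, 1, 2, 3, 4}.
    """

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if codes.size and not np.all((codes >= -1) & (codes <= 4)):
            bad = int(np.flatnonzero((codes < -1) | (codes > 4))[0])
            raise ValueError(f"invalid code {codes[bad]} at position {bad + 1}")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __str__(self) -> str:
        return decode_sequence(self)

    @property
    def length(self) -> int:
        return len(self)

    def has_ambiguity(self) -> bool:
        return bool(np.any(self.codes == AMBIG))


def encode_sequence(text: str) -> EncodedSequence:
    """Encode a DNA string (case-insensitive; N allowed) as codes 1..4.

    Raises ValueError naming the 1-based position of the first character
    outside {A, C, G, T, N, -}.
    """
    raw = np.frombuffer(text.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    lut = np.full(256, 99, dtype=np.int8)
    for base, code in _BASE_TO_CODE.items():
        lut[ord(base)] = code
    codes = lut[raw]
    bad = np.flatnonzero(codes == 99)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"invalid character {text[pos]!r} at position {pos + 1}")
    return EncodedSequence(codes)


def decode_sequence(seq: EncodedSequence) -> str:
    return "".join(_CODE_TO_BASE[int(c)] for c in seq.codes)


def dinucleotide_index(prev: int, cur: int) -> int:
    """Index 1..16 of the ordered base pair (prev, cur): n = prev + 4*(cur-1)."""
    if not (1 <= prev <= 4 and 1 <= cur <= 4):
        raise ValueError(f"base codes must be in 1..4, got ({prev}, {cur})")
    return prev + 4 * (cur - 1)


def dinucleotide_profile(seq: EncodedSequence) -> np.ndarray:
    """Per-position dinucleotide row index (0-based, length of seq).

    Position i >= 2 uses (seq[i-1], seq[i]); position 1 pairs the first base
    with itself.  Requires an ambiguity-free sequence.
    """
    codes = seq.codes.astype(np.int64)
    if codes.size == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(codes < 1):
        raise ValueError("sequence contains gap or ambiguity codes")
    prev = np.empty_like(codes)
    prev[0] = codes[0]
    prev[1:] = codes[:-1]
    return prev + 4 * (codes - 1) - 1


def reverse_complement(seq: EncodedSequence) -> EncodedSequence:
    """Reverse-complement an ambiguity-free encoded sequence."""
    codes = seq.codes
    if np.any(codes < 1):
        raise ValueError("sequence contains gap or ambiguity codes")
    return EncodedSequence(_COMPLEMENT[codes[::-1]])


def complement_code(code: int) -> int:
    return int(_COMPLEMENT[code])


@dataclass(frozen=True)
class CompositionModel:
    """Background composition of the analyzed sequence.

    base_freq: probabilities of A, T, C, G (indexed by code-1).
    p1: 16 dinucleotide prior probabilities, p1[n-1] = f(prev) * f(cur).
    p2 is the constant column prior 1/L1 and is supplied by the matrix side.
    """

    base_freq: np.ndarray
    p1: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.base_freq, dtype=np.float64)
        if f.shape != (4,):
            raise ValueError("base_freq must have 4 entries")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base_freq must be nonnegative and sum to 1")
        object.__setattr__(self, "base_freq", f)
        # row n = prev + 4*(cur-1): p1(n) = f(prev) f(cur)
        p1 = np.empty(16, dtype=np.float64)
        for cur in range(1, 5):
            for prev in range(1, 5):
                p1[prev + 4 * (cur - 1) - 1] = f[prev - 1] * f[cur - 1]
        object.__setattr__(self, "p1", p1)

    @classmethod
    def uniform(cls) -> "CompositionModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequence(cls, seq: EncodedSequence) -> "CompositionModel":
        """Measure base frequencies on the unambiguous positions of seq."""
        counts = np.bincount(seq.codes[seq.codes >= 1], minlength=5)[1:5]
        total = counts.sum()
        if total == 0:
            raise ValueError("sequence has no unambiguous bases")
        return cls(counts / total)
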