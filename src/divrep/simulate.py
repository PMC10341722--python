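"""Synthetic genomes with planted divergent repeat families.

A master repeat of length L1 is drawn uniformly; each planted copy receives
``round(x * L1 / 2)`` substitution events (uniform positions, drawn with
replacement, so a site can mutate repeatedly) plus a fixed number of
single-base indels.  Two copies then differ by ``x * L1`` substitution
events on average — ``x`` counts events per nucleotide, not observed
differences, which saturate below the event count because of multiple hits
at one site.  Copies are inserted at random non-overlapping positions of a
uniform host sequence, optionally half of them reverse-complemented, and
the exact planted intervals are recorded as ground truth.

Codon- and non-coding-shuffling controls rearrange a real genome while
preserving, respectively, the per-frame base composition of each gene and
the coding sequence itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from divrep.encoding import EncodedSequence, reverse_complement


@dataclass(frozen=True)
class SimConfig:
    """Planted-genome parameters (defaults: the full-scale benchmark)."""

    genome_length: int = 4_000_000
    repeat_length: int = 600
    n_copies: int = 1000
    x: float = 0.0
    n_indels: int = 2
    frac_reverse: float = 0.0
    min_gap: int | None = None  # default repeat_length + 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("x must be nonnegative")
        if self.n_copies * (self.repeat_length + 2) >= self.genome_length:
            raise ValueError("copies do not fit in the genome")
        if not 0.0 <= self.frac_reverse <= 1.0:
            raise ValueError("frac_reverse must be in [0, 1]")

    @property
    def gap(self) -> int:
        return self.min_gap if self.min_gap is not None else self.repeat_length + 100


@dataclass(frozen=True)
class PlantedCopy:
    """One planted repeat: final-genome interval (1-based incl.), orientation,
    inserted sequence and its mutation log."""

    start: int
    end: int
    reverse: bool
    sequence: EncodedSequence
    n_substitution_events: int
    indel_positions: tuple[int, ...]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one synthetic genome."""

    copies: list[PlantedCopy]
    master: EncodedSequence
    config: SimConfig

    def intervals(self) -> np.ndarray:
        """(n, 2) array of 1-based inclusive planted intervals, sorted."""
        iv = np.array([[c.start, c.end] for c in self.copies], dtype=np.int64)
        return iv[np.argsort(iv[:, 0])] if iv.size else iv.reshape(0, 2)


def make_master(L1: int, rng: np.random.Generator) -> EncodedSequence:
    """A uniform random ancestor repeat of length L1."""
    if L1 < 1:
        raise ValueError("L1 must be positive")
    return EncodedSequence(rng.integers(1, 5, L1).astype(np.int8))


def mutate_copy(
    master: EncodedSequence,
    x: float,
    n_indels: int,
    rng: np.random.Generator,
) -> tuple[EncodedSequence, dict]:
    """One divergent copy: round(x*L1/2) substitution events, then n_indels
    single-base insertions/deletions (equal probability, uniform position).
    """
    if x < 0:
        raise ValueError("x must be nonnegative")
    codes = master.codes.astype(np.int64).copy()
    L1 = codes.size
    n_sub = int(round(x * L1 / 2.0))
    positions = rng.integers(0, L1, n_sub)
    for pos in positions:
        old = codes[pos]
        # new base uniform among the other three
        new = rng.integers(1, 4)
        codes[pos] = new if new < old else new + 1
    indel_log = []
    for _ in range(n_indels):
        if codes.size > 1 and rng.random() < 0.5:
            pos = int(rng.integers(0, codes.size))
            codes = np.delete(codes, pos)
            indel_log.append(("del", pos))
        else:
            pos = int(rng.integers(0, codes.size + 1))
            base = int(rng.integers(1, 5))
            codes = np.insert(codes, pos, base)
            indel_log.append(("ins", pos))
    event_log = {
        "n_substitution_events": n_sub,
        "substitution_positions": positions.tolist(),
        "indels": indel_log,
    }
    return EncodedSequence(codes.astype(np.int8)), event_log


def make_test_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[EncodedSequence, SimTruth]:
    """Uniform host of ``genome_length`` bases with ``n_copies`` mutated
    copies of one master inserted at non-overlapping positions.

    Inserted copies keep a minimum host gap (default L1 + 100) between each
    other so every planted interval can be called independently; the first
    ``round(frac_reverse * n_copies)`` copies are reverse-complemented.
    The final genome length is the host length plus the inserted bases.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    host = rng.integers(1, 5, cfg.genome_length).astype(np.int8)
    master = make_master(cfg.repeat_length, rng)
    n_rev = int(round(cfg.frac_reverse * cfg.n_copies))
    rev_flags = np.zeros(cfg.n_copies, dtype=bool)
    rev_flags[:n_rev] = True
    rev_flags = rng.permutation(rev_flags)

    # host insertion points with pairwise gaps >= cfg.gap
    need = cfg.n_copies * cfg.gap
    if need >= cfg.genome_length:
        raise ValueError("cannot place copies with the required separation")
    for _ in range(100):
        raw = np.sort(rng.integers(0, cfg.genome_length - need, cfg.n_copies))
        points = raw + np.arange(cfg.n_copies) * cfg.gap
        if np.all(np.diff(points) >= cfg.gap):
            break
    else:  # pragma: no cover - spacing construction cannot fail
        raise RuntimeError("failed to place copies without overlap")

    pieces = []
    copies = []
    cursor = 0
    genome_pos = 0
    for k in range(cfg.n_copies):
        copy_seq, log = mutate_copy(master, cfg.x, cfg.n_indels, rng)
        reverse = bool(rev_flags[k])
        if reverse:
            copy_seq = reverse_complement(copy_seq)
        point = int(points[k])
        pieces.append(host[cursor:point])
        genome_pos += point - cursor
        start = genome_pos + 1
        pieces.append(copy_seq.codes)
        genome_pos += len(copy_seq)
        copies.append(
            PlantedCopy(
                start=start,
                end=genome_pos,
                reverse=reverse,
                sequence=copy_seq,
                n_substitution_events=log["n_substitution_events"],
                indel_positions=tuple(
                    pos for _, pos in log["indels"]
                ),
            )
        )
        cursor = point
    pieces.append(host[cursor:])
    genome = EncodedSequence(np.concatenate(pieces))
    # shuffle copy order in truth so orientation is not positionally banded
    order = rng.permutation(cfg.n_copies)
    copies = [copies[i] for i in order]
    return genome, SimTruth(copies=copies, master=master, config=cfg)


def shuffle_codons(
    genome: EncodedSequence,
    cds_intervals: list[tuple[int, int]],
    rng: np.random.Generator,
) -> EncodedSequence:
    """Permute the codon order within each coding interval.

    Intervals are 1-based inclusive; lengths not divisible by 3 and
    intervals overlapping an earlier one are skipped.  Codon-position base
    composition of every gene is left exactly unchanged.
    """
    codes = genome.codes.copy()
    covered = np.zeros(codes.size, dtype=bool)
    for start, end in cds_intervals:
        if start < 1 or end > codes.size or start > end:
            continue
        length = end - start + 1
        if length % 3 != 0 or covered[start - 1 : end].any():
            continue
        covered[start - 1 : end] = True
        block = codes[start - 1 : end].reshape(-1, 3)
        codes[start - 1 : end] = block[rng.permutation(block.shape[0])].ravel()
    return EncodedSequence(codes)


def shuffle_noncoding(
    genome: EncodedSequence,
    cds_intervals: list[tuple[int, int]],
    rng: np.random.Generator,
) -> EncodedSequence:
    """Permute all bases outside the union of coding intervals; CDS untouched."""
    codes = genome.codes.copy()
    coding = np.zeros(codes.size, dtype=bool)
    for start, end in cds_intervals:
        coding[max(start - 1, 0) : min(end, codes.size)] = True
    idx = np.flatnonzero(~coding)
    codes[idx] = codes[idx][rng.permutation(idx.size)]
    return EncodedSequence(codes)
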