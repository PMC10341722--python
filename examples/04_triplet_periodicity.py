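"""Measure codon-like period-3 structure in repeat family members.

Builds a family whose master has phase-dependent base preferences (as
protein-coding DNA does), recovers the members by a seeded scan, and
compares the triplet-periodicity statistic with and without the alignment.
"""

import numpy as np

from divrep.encoding import CompositionModel, EncodedSequence
from divrep.periodicity import family_phase_z, member_periodicity, phase_matrix
from divrep.pwm import matrix_from_sequence
from divrep.scan import estimate_background, find_hits, scan, shuffle_sequence
from divrep.simulate import mutate_copy

rng = np.random.default_rng(5)
probs = np.array([
    [0.55, 0.15, 0.15, 0.15],   # phase 1 favors A
    [0.15, 0.15, 0.55, 0.15],   # phase 2 favors C
    [0.15, 0.55, 0.15, 0.15],   # phase 3 favors T
])
master = EncodedSequence(np.array(
    [rng.choice([1, 2, 3, 4], p=probs[i % 3]) for i in range(600)], dtype=np.int8))

host = rng.integers(1, 5, 120_000).astype(np.int8)
gap = 120_000 // 31
pieces, pos = [], 0
for _ in range(30):
    pieces.append(host[pos : pos + gap - 600])
    pieces.append(mutate_copy(master, 1.0, 2, rng)[0].codes)
    pos += gap - 600
pieces.append(host[pos:])
genome = EncodedSequence(np.concatenate(pieces))

comp = CompositionModel.from_sequence(genome)
W = matrix_from_sequence(master, comp)
bg = estimate_background(shuffle_sequence(genome, rng), W, step=20, max_windows=800)
hits, n_lm, z_bar = find_hits(scan(genome, W, step=20), bg, 5.0, S=genome, W=W)
print(f"members found: {n_lm}, mean hit Z = {z_bar:.1f}")

aligned = [r.z for r in member_periodicity(hits)]
unaligned = [r.z for r in member_periodicity(hits, unaligned=True)]
print(f"triplet-periodicity z, aligned with the matrix: {np.mean(aligned):.2f}")
print(f"triplet-periodicity z, sequential frame:        {np.mean(unaligned):.2f}")

mats = [phase_matrix(h.alignment.aligned_seq, h.alignment.aligned_cols) for h in hits]
z = family_phase_z(mats)
print("family phase enrichment (rows A,T,C,G x phases 1..3):")
for base, row in zip("ATCG", z):
    print("  " + base + "  " + "  ".join(f"{v:7.1f}" for v in row))
print()
print("Positive cells mark (base, phase) combinations enriched beyond the")
print("margins; the alignment corrects indel frame shifts, so the aligned")
print("statistic exceeds the sequential-frame one.")
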