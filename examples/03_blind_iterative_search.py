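"""Discover a planted repeat family de novo, with no prior knowledge.

Runs the blind iterative procedure on a 400 kb genome carrying 100 copies
at x = 1.0: random matrices are refined on their own Z >= 3 seed hits,
rescanned at Z >= 5, and the best of several restarts kept.  Expect a few
minutes of compute; the found family is compared against the planted truth.
"""

import numpy as np

from divrep import IPConfig, SimConfig, find_families, make_test_genome, sensitivity

sim = SimConfig(genome_length=400_000, repeat_length=600, n_copies=100,
                x=1.0, seed=11)
genome, truth = make_test_genome(sim)
print(f"genome: {len(genome)} bases, 100 planted copies, x = {sim.x}")

cfg = IPConfig(step=20, background_windows=1500, inner_iters=6,
               restarts=2, early_stop_patience=2, n_families=1)
families = find_families(genome, cfg, rng=3)
fam = families[0]
print(f"family 1: {fam.n_members} members, mean Z = {fam.mean_z:.1f}")
print(f"restart trajectory (members, mean Z): {fam.trajectory}")

row = sensitivity(fam.hits, truth)
print(f"planted copies recovered: {row.n_detected}/{row.n_planted} "
      f"(sensitivity {row.sensitivity:.2f})")
print()
print("A successful restart 'snowballs': one seed hit on a planted copy")
print("pulls similar copies above threshold at the next scan, and the")
print("refined matrix converges onto the family; unsuccessful restarts")
print("stall at a small self-reinforcing noise family.")
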