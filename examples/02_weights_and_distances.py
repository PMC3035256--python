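"""Occupancy spectrum, core/shell/cloud weights, and profile distances.

Simulates a 14-genome pan-matrix with planted core/shell/cloud structure,
prints its occupancy spectrum, and compares distances under different
weight schemes.
"""

import numpy as np

from pantree import (
    SimulationConfig,
    jaccard,
    make_weights,
    manhattan,
    occupancy,
    simulate_panmatrix,
)

cfg = SimulationConfig(
    G=14, n_core=100, n_shell=150, n_cloud=250,
    shell_occupancy_range=(8, 13), cloud_occupancy_range=(1, 6), seed=1,
)
P = simulate_panmatrix(cfg)
spec = occupancy(P)
print(f"pan-matrix: {P.n_genomes} genomes x {P.n_families} families")
print("occupancy spectrum (families found in k genomes):")
print({k: v for k, v in spec.as_dict().items() if v})

for scheme in ("uniform", "drop_orfans", "shell", "cloud"):
    w = make_weights(P, scheme)
    D = manhattan(P, w).D
    off = D[np.triu_indices_from(D, k=1)]
    print(f"{scheme:>12}: W = {w.W:7.1f}, "
          f"mean pairwise distance = {off.mean():.4f}")

Dj = jaccard(P).D
print(f"{'jaccard':>12}: mean pairwise distance = "
      f"{Dj[np.triu_indices_from(Dj, k=1)].mean():.4f}")
# The shell scheme emphasizes widely conserved families (small distances),
# the cloud scheme the rare, strain-specific ones (larger distances);
# Jaccard ignores families absent from both genomes of a pair, so it is
# always at least as large as the uniform Manhattan distance.
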