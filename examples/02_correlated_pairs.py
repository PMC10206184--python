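"""Recover planted residue-residue couplings from a trajectory.

Builds a 100-residue chain whose motion model carries three correlations of
0.8 between chosen residue pairs, generates 20,000 frames, computes the
dynamics cross-correlation matrix and extracts every pair above the 0.5
threshold.  Exactly the planted pairs should appear, each with a correlation
close to 0.8.
"""

import numpy as np

from isodyn import AnalysisConfig, build_ideal_helix, compute_dccm, extract_correlated_pairs
from isodyn.synthetic import MotionSpec, generate_trajectory, plant_correlations

n_residues, n_frames = 100, 20_000
planted = [(5, 40, 0.8), (10, 50, 0.8), (20, 60, 0.8)]

spec = plant_correlations(
    MotionSpec(sigmas=np.full(n_residues, 0.5), correlation=np.eye(n_residues),
               n_frames=n_frames, seed=42),
    planted,
)
trajectory = generate_trajectory(build_ideal_helix(n_residues), spec)

# the generator adds no rigid-body motion, so statistics run in raw mode
config = AnalysisConfig(align=False, dccm_threshold=0.5)
dccm = compute_dccm(trajectory, config)
pairs = extract_correlated_pairs(dccm, config)

print(f"planted couplings: {[(i + 1, j + 1, rho) for i, j, rho in planted]}")
print(f"pairs above C_ij > {config.dccm_threshold}:")
for p in pairs:
    print(f"  {p.label:>10s}  C = {p.correlation:+.3f}  ({p.pair_class})")
print("\nEach recovered correlation should sit within sampling error "
      f"(~{3 / np.sqrt(n_frames):.3f}) of the planted 0.8.")
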