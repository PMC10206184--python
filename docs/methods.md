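# Methods

This note records the models, conventions and numerical choices behind
`isodyn`, and what its validation does and does not demonstrate.

## Coordinate model and formats

Structures are ordered atom lists with 1-based residue indices and
single-letter chains, matching how residues are quoted in the structural
literature (K395, V76).  Trajectories are `(F, N, 3)` arrays in Å over a
fixed topology with a capture interval in picoseconds; snapshot *k* sits at
time `(k+1)·interval` — the t=0 structure is not stored, the endpoint is, so
a 650 ns run captured every 25 ps holds exactly 26 000 snapshots.
Multi-model PDB (fixed-column `ATOM` records, `MODEL`/`ENDMDL`) is the
canonical text format; a per-frame XYZ dialect (atom-count header, then
`element x y z` lines) is accepted for synthetic data.  Binary formats
(DCD/XTC), mmCIF, connectivity perception and hydrogen placement are out of
scope.  Parsing is strict: models that disagree in atom count or identity
order produce an error naming the offending model rather than a silently
truncated ensemble, and coordinates round-trip bit-identically at PDB's
3-decimal precision.

## Superposition and alignment

Rigid superposition is the Kabsch algorithm: SVD of the cross-covariance of
centred point sets with a determinant correction that excludes reflections.
Degenerate (collinear) selections are rejected because the rotation about
the line is under-determined.  Optimality is validated against an
independent brute-force oracle (dense Euler-angle grid plus simplex
refinement) to 1e-5 Å on random instances.

Trajectory alignment iterates to the mean structure: fit every frame to the
current mean of the selection, recompute the mean, repeat until the mean
moves < 1e-9 Å (typically 2–3 passes, vectorised over frames with batched
3×3 SVDs).  Starting from the raw frame mean (rather than frame 0) makes an
already-aligned trajectory an exact fixed point, so alignment is idempotent
to machine precision.  The default selection is every Cα of every chain —
the complex is analysed as a whole — and is configurable because published
analyses are often silent on exclusions.  No mass weighting is applied
anywhere: the metrics are defined on Cα atoms only.

## Movement statistics

* **RMSD series**: per-frame root-mean-square Cα deviation from the
  alignment reference (the converged mean by default; frame 0 in raw,
  unaligned mode).  Times are `frame_index × capture_interval`.
* **RMSF profile**: per-residue fluctuation about the time-average position
  on aligned frames; requires ≥ 2 frames.
* **Percent of total movement** normalises each residue's RMSF across the
  conformers being compared, `p(c,i) = 100·RMSF(c,i)/Σ_c′RMSF(c′,i)` — the
  stacked-bar reading in which the four conformers' shares at one residue
  sum to 100.  The alternative normalisation (per-conformer chain total) is
  deliberately not used.  Residues with zero RMSF in every conformer are
  reported as explicitly undefined (`pd.NA`), never as NaN arithmetic.
* **Region scores** sum RMSF over a named chain/range set (e.g. the
  19-residue loop, the C-terminal polybasic region).  Conformers are ranked
  by ascending score — the least-moving region marks the most stable
  conformer — with lexicographic tie-breaking for deterministic output.

## Cross-correlation analysis

The dynamics cross-correlation matrix uses the standard normalised
equal-time estimator on aligned Cα fluctuations,
`C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`.  Residues whose displacement
variance is below 1e-12 Å² (exactly constant coordinates leave only float
residue) are carried as undefined markers — never coerced to zero.  Pair
extraction keeps off-diagonal entries with `C_ij > τ` (signed mode, default
τ = 0.5, strict inequality) or `|C_ij| > τ` (absolute mode, provided because
heat maps colour negative couplings too); scopes restrict pairs to two
disjoint same-chain regions (loop × polybasic region) or to inter-chain
contacts.  Labels follow the literature's one-letter convention
("V76-E197").

Mean-structure alignment absorbs six rigid-body degrees of freedom, which
biases correlation estimates slightly toward zero (≈ −0.015 at 100 residues
in our checks).  Ground-truth recovery tests therefore run in raw mode on
generator output that contains no rigid contamination; the aligned path is
validated separately by its invariance under injected rigid motion (below).

## Equilibrium diagnostics

Each scalar series (RMSD, surface area, hydrogen bonds, secondary-structure
fractions, passthrough energy) is split into 5 equal blocks (remainder
frames dropped from the front); the series has plateaued when the last two
block means differ by at most `tol` (default 1) pooled within-block standard
deviations of those two blocks.  A constant series always passes; a drifting
series whose block-to-block step exceeds its within-block spread fails.
This is a deliberately cheap screen, not a statistical equilibration proof.

## Surface metrics

* **SASA** is Shrake–Rupley: each atom's van-der-Waals sphere (C 1.70,
  N 1.55, O 1.52, S 1.80, H 1.20 Å; 1.70 default only when explicitly
  enabled) is inflated by the probe radius (1.4 Å) and sampled with 960
  deterministic golden-spiral points; a point survives if it lies outside
  every neighbour's inflated sphere.  An isolated atom recovers the analytic
  `4π(r+p)²` to quadrature accuracy (< 1 %).  Because the test points are
  fixed in space relative to each atom, occlusion monotonicity (adding an
  atom never increases anyone's SASA) and translation invariance are
  *exact*, while rotating the whole structure re-rolls the quadrature and
  agrees only to ~0.1–0.5 % at 960 points.  The converse trade (orienting
  points by neighbour geometry) would make rotation exact but monotonicity
  approximate; exactness of monotonicity was chosen.  Doubling the point
  count halves the quadrature error, which the suite checks.
* **Hydrogen bonds** use a geometric criterion: donor–acceptor heavy-atom
  distance ≤ 3.5 Å, same-residue pairs excluded, plus a D–H···A angle
  ≥ 120° whenever the model actually carries hydrogens (Cα/backbone models
  usually do not, and the criterion degrades gracefully to distance-only).
* **Secondary structure** is a simplified φ/ψ-box assignment — helix for
  φ∈[−100°,−30°] ∧ ψ∈[−80°,−5°], sheet for φ∈[−180°,−80°] ∧
  ψ∈[80°,180°]∪[−180°,−170°], else coil — over residues with a complete
  backbone context; terminal residues count in neither numerator nor
  denominator.  It is explicitly **not** DSSP-compatible: its role is a
  per-frame equilibrium indicator, not per-residue annotation.

## Conservation scoring

Conservation is measured against a named reference row (the sequence whose
structure is being painted), not a column consensus: for each column where
the reference is ungapped, `match_fraction` is the share of non-gap rows
carrying the reference residue (the reference counts as a match of itself).
Categories: *gap* when the column is gapped in a majority of rows (> 0.5),
*strict* at fraction 1.0, *high* strictly above 0.9 (a column at exactly
0.9 is *variable*), else *variable*.  Gap rows are excluded from the
denominator so fragmentary orthologs do not dilute the score.  Alignment
construction, phylogenetic weighting and entropy scores are out of scope —
the module consumes any pre-computed aligned FASTA.  For structure painting,
categories map to B-factor values 1.00 / 0.90 / 0.50 / 0.00 (configurable).

## Isoform coordinate mapping

A mapping is an ordered list of non-overlapping insertion/deletion edits
stated A→B.  Positions N-terminal of all edits are fixed points; later
positions shift by the cumulative signed edit length; positions inside a
span the target lacks raise an explicit no-correspondence error (no
nearest-neighbour snapping).  The inverse mapping is derived by swapping
edit kinds at translated offsets, and the whole machinery is validated
position-by-position against an explicit letter-by-letter alignment oracle
on random mappings.  The shipped chaperone fixture places its 49-residue
deletion at residues 100–148 of the long isoform: the two published
coordinate correspondences (395→346, 324→275) constrain only the cumulative
offset, so any span fully N-terminal of residue 324 is equivalent — a
fixture convention, not a biological claim.

## Synthetic ground truth

The generator draws per-frame residue displacements from a multivariate
Gaussian: identical correlation matrix per axis, isotropic per-residue
amplitudes σᵢ.  Consequences used throughout validation: the expected DCCM
equals the planted correlation matrix exactly, and the expected RMSF is
√3·σᵢ.  Planting correlations on disjoint pairs at |ρ| ≤ 0.8 keeps the
matrix positive semidefinite (checked; violations report the smallest
eigenvalue).  Optional rigid-body contamination applies an independent
random proper rotation (axis uniform on the sphere, angle uniform up to a
cap, default 30°) and translation (uniform, default 5 Å) to each frame;
internal distances are untouched, so alignment-enabled statistics must be
invariant — the suite requires < 2 % change in RMSF, region scores and DCCM.

The two-chain fixture emulates a GTPase–chaperone complex: chain R of 211
residues carrying a 19-residue loop (residues 75–93) and a C-terminal
polybasic region (202–208), chain S of 558 residues, both as Cα helices;
four conformers share a 0.30 Å background σ and differ in loop/polybasic
amplitudes (σ_PBR 0.15/0.45/0.60/0.80 Å) so exactly one conformer is the
constructed stability-ranking winner; the designated long conformer carries
three loop↔PBR and two loop↔chain-S planted correlations of 0.8.  Loop and
polybasic boundaries are fixture conventions chosen to be consistent with
the residue numbering conventions of the system emulated; they are user
data in real analyses.

**What passing does not show**: the Gaussian model has no physics — no
potential, no solvent, no side chains, no anharmonicity, no time
correlation (frames are exchangeable, which the DCCM shuffle-invariance
test exploits).  Recovery of planted parameters validates the *estimators*,
not any simulation methodology, and real trajectories additionally face
force-field and sampling error that no test here touches.

## Problem sizes and tolerances

Statistical recovery runs at the sizes where its closed-form tolerances are
comfortably resolved: RMSF recovery at 20 000 frames × 50 residues (2 %
tolerance vs ≈ 0.4 % sampling error), correlation recovery at 50 000 frames
× 100 residues (±0.01 vs ≈ 0.002 sampling error), rigid-motion invariance
at 2 000 frames × 60 residues.  The end-to-end pipeline demonstration uses
the full 769-residue complex at a few hundred frames.  Fixed seeds make
every number reproducible; `scripts/acceptance.py` derives all of its seeds
from its `--seed` argument.

## Known limitations

* PDB support covers `ATOM`/`HETATM` coordinate records only (no altLoc
  handling, no insertion codes, no mmCIF).
* The DCCM is the scalar dot-product estimator; it cannot distinguish
  parallel from antiparallel motion directions beyond the sign, and reports
  no statistical significance.
* SASA rotation invariance is quadrature-limited (see above); raise
  `n_points` when sub-0.1 % rotational stability matters.
* The secondary-structure boxes misclassify left-handed helices and
  polyproline II as coil by construction.
* Hydrogen-bond counting is O(donors × acceptors) — adequate for the
  per-frame diagnostic scale it serves.
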