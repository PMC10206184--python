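"""Trajectory ensemble statistics.

The quantities here are the standard vocabulary for describing how a protein
complex moves over a simulation:

* **RMSD** — per-frame root-mean-square deviation of Cα atoms from a
  reference after optimal rigid superposition (global movement over time);
* **RMSF** — per-residue root-mean-square fluctuation about the
  time-average position (where the movement is);
* **percent of total movement** — each residue's RMSF expressed as a share
  of that residue's summed RMSF across several conformers, the stacked-bar
  reading used to compare starting conformations;
* **region scores / ranking** — summed RMSF over a named residue region
  (e.g. a loop or polybasic region), lowest total = most stable conformer;
* **DCCM** — the dynamics cross-correlation matrix
  ``C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`` on aligned Cα
  fluctuations, with thresholded extraction of correlated residue pairs;
* **equilibrium diagnostics** — block-mean plateau checks on scalar series.

Superposition uses the Kabsch algorithm (SVD with determinant correction,
no reflections); trajectories are aligned to their converged mean structure,
the convention under which the RMSF and DCCM definitions are internally
consistent.  All statistics are Cα-based with uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .structure import StructureModel, Trajectory

__all__ = [
    "AnalysisConfig",
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "RegionDefinition",
    "RegionScore",
    "Dccm",
    "CorrelatedPair",
    "EquilibriumReport",
    "kabsch_superpose",
    "align_trajectory",
    "rmsd_series",
    "rmsf_profile",
    "percent_total_movement",
    "region_movement_score",
    "rank_conformers",
    "compute_dccm",
    "extract_correlated_pairs",
    "equilibrium_diagnostics",
]

#: Three-letter → one-letter amino-acid codes for pair labels like "V76-E197".
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class AnalysisConfig:
    """Knobs shared across the trajectory statistics.

    ``selection_atom_name``/``selection_chains`` pick the atoms used for
    superposition and statistics (default: every Cα of every chain — the
    complex is analyzed as a whole).  ``dccm_threshold`` is the pair
    extraction cutoff (signed ``C_ij > τ`` by default; ``absolute`` uses
    ``|C_ij| > τ``).  ``equil_blocks``/``equil_tol`` parameterize the
    block-mean plateau check.
    """

    selection_atom_name: str = "CA"
    selection_chains: tuple[str, ...] | None = None
    align: bool = True
    reference: Literal["mean", "first"] = "mean"
    dccm_threshold: float = 0.5
    threshold_mode: Literal["signed", "absolute"] = "signed"
    strict_threshold: float = 1.0
    high_threshold: float = 0.9
    capture_interval_ps: float = 25.0
    equil_blocks: int = 5
    equil_tol: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.dccm_threshold <= 1.0):
            raise ValueError(f"dccm_threshold must be in (0, 1], got {self.dccm_threshold}")
        if self.equil_blocks < 2:
            raise ValueError("equil_blocks must be >= 2")

    def selection_indices(self, structure: StructureModel) -> np.ndarray:
        idx = []
        for i, a in enumerate(structure.atoms):
            if self.selection_atom_name and a.name != self.selection_atom_name:
                continue
            if self.selection_chains is not None and a.chain_id not in self.selection_chains:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation; apply as ``x' = R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


class DegenerateGeometryError(ValueError):
    """Superposition target is collinear or otherwise under-determined."""


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal rigid superposition of *mobile* onto *reference* (Kabsch).

    The returned transform minimizes the RMSD between the selected point
    pairs over all proper rotations and translations; reflections are
    excluded by the determinant correction.  At least three non-collinear
    points are required.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if selection is not None:
        P = P[selection]
        Q = Q[selection]
    if P.shape != Q.shape:
        raise ValueError(f"point-count mismatch: mobile {P.shape} vs reference {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError(f"need >= 3 points for superposition, got {P.shape[0]}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    for pts, label in ((P0, "mobile"), (Q0, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1e-30):
            raise DegenerateGeometryError(
                f"{label} points are collinear; rotation is under-determined"
            )
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _batched_kabsch(frames_sel: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame optimal (R, t) for (F, M, 3) selections onto one (M, 3) reference."""
    pc = frames_sel.mean(axis=1, keepdims=True)          # (F, 1, 3)
    qc = reference.mean(axis=0)                          # (3,)
    P0 = frames_sel - pc
    Q0 = reference - qc
    H = np.einsum("fma,mb->fab", P0, Q0)                 # (F, 3, 3)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fab,fcb->fac", Vt.transpose(0, 2, 1), U))
    D = np.repeat(np.eye(3)[None], len(H), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fab,fbc,fdc->fad", Vt.transpose(0, 2, 1), D, U)
    t = qc - np.einsum("fab,fb->fa", R, pc[:, 0, :])
    return R, t


def align_trajectory(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> Trajectory:
    """Superpose every frame onto the converged mean structure of the selection.

    Two-pass (iterated) mean-structure alignment: every frame is fitted to
    the current mean selection coordinates, the mean is recomputed, and the
    cycle repeats until the mean moves less than *tol* Å (typically 2–3
    passes).  Starting from the raw mean makes an already-aligned trajectory
    an exact fixed point (the first pass applies identity transforms).  The
    whole frame is transformed; only the selection drives the fit.
    """
    config = config or AnalysisConfig()
    sel = config.selection_indices(traj.topology)
    if sel.size < 3:
        raise ValueError(
            f"alignment selection resolves {sel.size} atoms; need >= 3"
        )
    frames = traj.frames.copy()
    reference = frames[:, sel, :].mean(axis=0)
    for _ in range(max_iter):
        R, t = _batched_kabsch(frames[:, sel, :], reference)
        frames = np.einsum("fab,fnb->fna", R, frames) + t[:, None, :]
        new_reference = frames[:, sel, :].mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_reference - reference, axis=1)))
        reference = new_reference
        if shift < tol:
            break
    return Trajectory(
        topology=traj.topology.with_coordinates(frames[0]),
        frames=frames,
        capture_interval_ps=traj.capture_interval_ps,
        name=traj.name,
    )


@dataclass
class RmsdSeries:
    conformer: str
    times_ps: np.ndarray
    values: np.ndarray

    def to_tsv(self) -> str:
        lines = ["frame\ttime_ps\trmsd_A"]
        for i, (t, v) in enumerate(zip(self.times_ps, self.values)):
            lines.append(f"{i + 1}\t{t:g}\t{v:.6f}")
        return "\n".join(lines) + "\n"


def rmsd_series(traj: Trajectory, config: AnalysisConfig | None = None) -> RmsdSeries:
    """Per-frame Cα RMSD from the alignment reference (global movement).

    With ``config.align`` the trajectory is first mean-structure aligned and
    deviations are measured from the mean (or from frame 0 with
    ``reference="first"``); with alignment disabled, raw deviations from
    frame 0 are reported.
    """
    config = config or AnalysisConfig()
    sel = config.selection_indices(traj.topology)
    if sel.size == 0:
        raise ValueError("selection resolves no atoms")
    work = align_trajectory(traj, config) if config.align else traj
    coords = work.frames[:, sel, :]
    if config.reference == "mean" and config.align:
        ref = coords.mean(axis=0)
    else:
        ref = coords[0]
    values = np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=2), axis=1))
    return RmsdSeries(conformer=traj.name, times_ps=work.times_ps, values=values)


@dataclass
class RmsfProfile:
    conformer: str
    residue_keys: list[tuple[str, int]]
    values: np.ndarray

    def as_dict(self) -> dict[tuple[str, int], float]:
        return dict(zip(self.residue_keys, self.values))

    def to_tsv(self) -> str:
        lines = ["chain\tresidue_index\trmsf_A"]
        for (c, r), v in zip(self.residue_keys, self.values):
            lines.append(f"{c}\t{r}\t{v:.6f}")
        return "\n".join(lines) + "\n"


def rmsf_profile(traj: Trajectory, config: AnalysisConfig | None = None) -> RmsfProfile:
    """Per-residue Cα RMSF about the time-average position on aligned frames."""
    config = config or AnalysisConfig()
    if traj.n_frames < 2:
        raise ValueError(f"RMSF needs >= 2 frames, got {traj.n_frames}")
    sel = config.selection_indices(traj.topology)
    if sel.size == 0:
        raise ValueError("selection resolves no atoms")
    work = align_trajectory(traj, config) if config.align else traj
    coords = work.frames[:, sel, :]
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    keys = [traj.topology.atoms[i].residue_key for i in sel]
    return RmsfProfile(conformer=traj.name, residue_keys=keys, values=rmsf)


def percent_total_movement(profiles: Sequence[RmsfProfile]) -> pd.DataFrame:
    """Share of each residue's movement attributable to each conformer.

    ``p(c, i) = 100 · RMSF(c, i) / Σ_c' RMSF(c', i)``; rows are residues,
    columns conformers, every row sums to 100.  Residues whose RMSF is zero
    in every conformer get ``pd.NA`` (undefined), never a division artifact.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two conformer profiles")
    keys0 = profiles[0].residue_keys
    for p in profiles[1:]:
        if p.residue_keys != keys0:
            a, b = set(keys0), set(p.residue_keys)
            raise ValueError(
                f"residue keys differ between {profiles[0].conformer!r} and "
                f"{p.conformer!r}: symmetric difference {sorted(a ^ b)}"
            )
    mat = np.stack([p.values for p in profiles], axis=1)  # (residues, conformers)
    totals = mat.sum(axis=1)
    index = pd.MultiIndex.from_tuples(keys0, names=["chain", "residue_index"])
    out = pd.DataFrame(
        index=index, columns=[p.conformer for p in profiles], dtype="Float64"
    )
    defined = totals > 0
    pct = np.full_like(mat, np.nan)
    pct[defined] = 100.0 * mat[defined] / totals[defined, None]
    for j, p in enumerate(profiles):
        col = pd.array(pct[:, j], dtype="Float64")
        col[~defined] = pd.NA
        out[p.conformer] = col
    return out


@dataclass(frozen=True)
class RegionDefinition:
    """A named set of residue ranges on one chain (inclusive, 1-based)."""

    name: str
    chain: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"region {self.name}: empty range {start}-{end}")
            if start <= prev_end:
                raise ValueError(f"region {self.name}: ranges overlap or unsorted")
            prev_end = end

    def residue_keys(self) -> list[tuple[str, int]]:
        return [
            (self.chain, r)
            for start, end in self.ranges
            for r in range(start, end + 1)
        ]

    def __contains__(self, key: tuple[str, int]) -> bool:
        chain, idx = key
        return chain == self.chain and any(s <= idx <= e for s, e in self.ranges)


@dataclass(frozen=True)
class RegionScore:
    conformer: str
    region: str
    score: float


def region_movement_score(profile: RmsfProfile, region: RegionDefinition) -> RegionScore:
    """Summed RMSF over the region's residues — total movement of the region."""
    values = profile.as_dict()
    total = 0.0
    for key in region.residue_keys():
        if key not in values:
            raise ValueError(
                f"region {region.name!r} residue {key[0]}:{key[1]} absent from "
                f"profile {profile.conformer!r}"
            )
        total += values[key]
    return RegionScore(conformer=profile.conformer, region=region.name, score=total)


def rank_conformers(scores: Sequence[RegionScore], by_region: str) -> list[str]:
    """Conformers ordered by ascending region score (most stable first).

    Ties break lexicographically on conformer name, keeping output
    deterministic.
    """
    relevant = {s.conformer: s.score for s in scores if s.region == by_region}
    all_conformers = {s.conformer for s in scores}
    missing = all_conformers - set(relevant)
    if missing:
        raise ValueError(
            f"no {by_region!r} score for conformer(s): {sorted(missing)}"
        )
    return sorted(relevant, key=lambda c: (relevant[c], c))


@dataclass
class Dccm:
    """Symmetric residue×residue normalized cross-correlation matrix.

    ``undefined`` lists residues with zero displacement variance; their rows
    and columns hold NaN markers rather than silent zeros.
    """

    residue_keys: list[tuple[str, int]]
    matrix: np.ndarray
    undefined: list[tuple[str, int]] = field(default_factory=list)
    residue_names: dict[tuple[str, int], str] = field(default_factory=dict)

    def value(self, key_i: tuple[str, int], key_j: tuple[str, int]) -> float:
        i = self.residue_keys.index(key_i)
        j = self.residue_keys.index(key_j)
        return float(self.matrix[i, j])

    def to_tsv(self) -> str:
        labels = [f"{c}:{r}" for c, r in self.residue_keys]
        lines = ["residue\t" + "\t".join(labels)]
        for lab, row in zip(labels, self.matrix):
            lines.append(lab + "\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


def compute_dccm(traj: Trajectory, config: AnalysisConfig | None = None) -> Dccm:
    """Dynamics cross-correlation matrix of Cα fluctuations on aligned frames.

    ``C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)`` with
    ``Δr_i(t) = r_i(t) − ⟨r_i⟩``.  Values lie in [−1, 1] with a unit
    diagonal; residues with zero variance are reported as undefined.
    """
    config = config or AnalysisConfig()
    if traj.n_frames < 3:
        raise ValueError(f"DCCM needs >= 3 frames, got {traj.n_frames}")
    sel = config.selection_indices(traj.topology)
    if sel.size == 0:
        raise ValueError("selection resolves no atoms")
    work = align_trajectory(traj, config) if config.align else traj
    coords = work.frames[:, sel, :]
    delta = coords - coords.mean(axis=0)
    F = delta.shape[0]
    cov = np.einsum("fia,fja->ij", delta, delta) / F
    var = np.diag(cov).copy()
    # floor guards against float residue of exactly-constant coordinates
    undefined_mask = var <= 1e-12
    denom = np.sqrt(np.outer(np.where(undefined_mask, 1.0, var),
                             np.where(undefined_mask, 1.0, var)))
    C = cov / denom
    C[undefined_mask, :] = np.nan
    C[:, undefined_mask] = np.nan
    np.fill_diagonal(C, np.where(undefined_mask, np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0, out=C)
    keys = [traj.topology.atoms[i].residue_key for i in sel]
    names = {
        traj.topology.atoms[i].residue_key: traj.topology.atoms[i].residue_name
        for i in sel
    }
    undefined = [k for k, m in zip(keys, undefined_mask) if m]
    return Dccm(residue_keys=keys, matrix=C, undefined=undefined, residue_names=names)


@dataclass(frozen=True)
class CorrelatedPair:
    key_i: tuple[str, int]
    key_j: tuple[str, int]
    correlation: float
    pair_class: Literal["intra_chain", "inter_chain"]
    label: str


def _residue_label(dccm: Dccm, key: tuple[str, int]) -> str:
    name3 = dccm.residue_names.get(key, "UNK")
    one = _THREE_TO_ONE.get(name3.upper(), "X")
    return f"{one}{key[1]}"


def extract_correlated_pairs(
    dccm: Dccm,
    config: AnalysisConfig | None = None,
    scope: Literal["intra_pair_of_regions", "inter_chain", "all"] = "all",
    regions: tuple[RegionDefinition, RegionDefinition] | None = None,
) -> list[CorrelatedPair]:
    """Residue pairs whose correlation exceeds the threshold, within a scope.

    ``signed`` mode keeps ``C_ij > τ`` (the convention when only positive
    couplings are reported); ``absolute`` keeps ``|C_ij| > τ``.  Scopes:
    ``intra_pair_of_regions`` — i in one region and j in the other, both on
    the same chain (e.g. loop × polybasic region); ``inter_chain`` — i and j
    on different chains; ``all`` — every off-diagonal pair.  Labels use
    one-letter residue codes, e.g. ``"V76-E197"``.
    """
    config = config or AnalysisConfig()
    tau = config.dccm_threshold
    if scope == "intra_pair_of_regions":
        if regions is None or len(regions) != 2:
            raise ValueError("intra_pair_of_regions scope needs exactly two regions")
        ra, rb = regions
        if ra.chain != rb.chain:
            raise ValueError("paired regions must lie on the same chain")
        if set(ra.residue_keys()) & set(rb.residue_keys()):
            raise ValueError(f"regions {ra.name!r} and {rb.name!r} overlap")
    keys = dccm.residue_keys
    out: list[CorrelatedPair] = []
    n = len(keys)
    for i in range(n):
        for j in range(i + 1, n):
            v = dccm.matrix[i, j]
            if np.isnan(v):
                continue
            passes = abs(v) > tau if config.threshold_mode == "absolute" else v > tau
            if not passes:
                continue
            ki, kj = keys[i], keys[j]
            if scope == "inter_chain" and ki[0] == kj[0]:
                continue
            if scope == "intra_pair_of_regions":
                in_pair = (ki in regions[0] and kj in regions[1]) or (
                    ki in regions[1] and kj in regions[0]
                )
                if not in_pair:
                    continue
            pair_class = "intra_chain" if ki[0] == kj[0] else "inter_chain"
            out.append(
                CorrelatedPair(
                    key_i=ki,
                    key_j=kj,
                    correlation=float(v),
                    pair_class=pair_class,
                    label=f"{_residue_label(dccm, ki)}-{_residue_label(dccm, kj)}",
                )
            )
    return out


def pairs_to_tsv(pairs: Sequence[CorrelatedPair]) -> str:
    lines = ["chain_i\tres_i\tchain_j\tres_j\tcorrelation\tclass\tlabel"]
    for p in pairs:
        lines.append(
            f"{p.key_i[0]}\t{p.key_i[1]}\t{p.key_j[0]}\t{p.key_j[1]}\t"
            f"{p.correlation:.4f}\t{p.pair_class}\t{p.label}"
        )
    return "\n".join(lines) + "\n"


@dataclass
class SeriesDiagnostic:
    label: str
    block_means: np.ndarray
    plateau: bool


@dataclass
class EquilibriumReport:
    series: list[SeriesDiagnostic]

    @property
    def all_plateaued(self) -> bool:
        return all(s.plateau for s in self.series)

    def to_tsv(self) -> str:
        lines = ["series\tplateau\tblock_means"]
        for s in self.series:
            means = ",".join(f"{m:.6g}" for m in s.block_means)
            lines.append(f"{s.label}\t{str(s.plateau).lower()}\t{means}")
        return "\n".join(lines) + "\n"


def equilibrium_diagnostics(
    series: dict[str, np.ndarray],
    config: AnalysisConfig | None = None,
) -> EquilibriumReport:
    """Block-mean plateau check on labeled scalar time series.

    Each series is split into ``equil_blocks`` equal blocks (remainder frames
    dropped from the front); it has plateaued when the last two block means
    differ by at most ``equil_tol`` pooled within-block standard deviations
    of those two blocks.  This is the usual cheap equilibration diagnostic
    for per-frame metrics (energy, surface area, RMSD, ...).
    """
    config = config or AnalysisConfig()
    blocks = config.equil_blocks
    out: list[SeriesDiagnostic] = []
    for label, values in series.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2 * blocks:
            raise ValueError(
                f"series {label!r} has {values.size} points; need >= {2 * blocks} "
                f"for {blocks} blocks"
            )
        usable = values[values.size % blocks:]
        split = usable.reshape(blocks, -1)
        means = split.mean(axis=1)
        last, penult = split[-1], split[-2]
        pooled_std = float(np.sqrt((last.var(ddof=0) + penult.var(ddof=0)) / 2.0))
        diff = abs(float(means[-1] - means[-2]))
        plateau = diff <= config.equil_tol * pooled_std
        out.append(SeriesDiagnostic(label=label, block_means=means, plateau=plateau))
    return EquilibriumReport(series=out)
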