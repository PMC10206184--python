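"""Per-frame structural metrics used as equilibrium diagnostics.

Three cheap, deterministic metrics whose per-frame time series indicate
whether a simulation has settled:

* Shrake–Rupley solvent-accessible surface area with deterministic
  golden-spiral test points (bit-reproducible, no random sphere sampling);
* geometric hydrogen-bond counts (heavy-atom distance criterion, an optional
  donor–H–acceptor angle when hydrogens are present);
* simplified φ/ψ-box secondary-structure fractions (helix / sheet / coil).

The secondary-structure boxes are a diagnostic, deliberately simpler than
DSSP: only the fraction of residues in each class is tracked, not
per-residue assignments for publication figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel, Trajectory

__all__ = [
    "SasaResult",
    "HBondCount",
    "SecondaryStructureFractions",
    "VDW_RADII",
    "shrake_rupley_sasa",
    "count_hbonds",
    "secondary_structure_fractions",
]

#: van der Waals radii (Å) used for SASA; unknown elements fall back to the
#: default only when explicitly allowed.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.70


@dataclass
class SasaResult:
    per_atom: np.ndarray
    per_residue: dict[tuple[str, int], float]
    total: float
    probe_radius: float
    n_points: int


def _golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    allow_default_radius: bool = False,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's sphere is inflated by the probe radius and sampled with
    *n_points* golden-spiral test points; a point is exposed when it lies
    outside every neighbouring atom's inflated sphere.  Per-atom SASA is
    ``4π(r+p)² · exposed/n_points``; an isolated atom therefore recovers the
    analytic sphere area to quadrature accuracy.
    """
    atoms = structure.atoms
    if not atoms:
        raise ValueError("structure has no atoms")
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el in VDW_RADII:
            radii[i] = VDW_RADII[el]
        elif allow_default_radius:
            radii[i] = DEFAULT_RADIUS
        else:
            raise ValueError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.chain_id}:{a.residue_index}:{a.name}); "
                f"enable allow_default_radius to use {DEFAULT_RADIUS} Å"
            )
    coords = structure.coordinates
    inflated = radii + probe_radius
    sphere = _golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], inflated[i] + inflated.max())
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < inflated[i] + inflated[j]
        ]
        points = coords[i] + inflated[i] * sphere
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r = inflated[neighbors]
            d2 = np.sum((points[:, None, :] - nb_coords[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nb_r**2)[None, :], axis=1)
            exposed = int(np.sum(~buried))
        else:
            exposed = n_points
        per_atom[i] = 4.0 * math.pi * inflated[i] ** 2 * exposed / n_points
    per_residue: dict[tuple[str, int], float] = {}
    for a, v in zip(atoms, per_atom):
        per_residue[a.residue_key] = per_residue.get(a.residue_key, 0.0) + float(v)
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_points=n_points,
    )


@dataclass
class HBondCount:
    count: int
    d_max: float
    angle_min: float | None


def _bonded_hydrogens(structure: StructureModel, donor_idx: int) -> list[int]:
    donor = structure.atoms[donor_idx]
    out = []
    for j, a in enumerate(structure.atoms):
        if a.element.upper() != "H" or a.residue_key != donor.residue_key:
            continue
        if np.linalg.norm(a.position - donor.position) < 1.3:
            out.append(j)
    return out


def count_hbonds(
    frame: StructureModel,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> HBondCount:
    """Geometric hydrogen-bond count between donor and acceptor selections.

    A donor–acceptor pair counts when the heavy-atom distance is ≤ *d_max* Å
    and, if the donor has bonded hydrogens in the model, some D–H···A angle
    is ≥ *angle_min* degrees.  Distance-only when hydrogens are absent
    (Cα/backbone models rarely carry them).  Same-residue pairs are excluded.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    coords = frame.coordinates
    has_any_h = any(a.element.upper() == "H" for a in frame.atoms)
    count = 0
    for di in donors:
        d_atom = frame.atoms[di]
        hydrogens = _bonded_hydrogens(frame, int(di)) if has_any_h else []
        for ai in acceptors:
            if ai == di:
                continue
            a_atom = frame.atoms[ai]
            if a_atom.residue_key == d_atom.residue_key:
                continue
            dist = float(np.linalg.norm(coords[ai] - coords[di]))
            if dist > d_max:
                continue
            if hydrogens:
                ok = False
                for hi in hydrogens:
                    dh = coords[hi] - coords[di]
                    ha = coords[ai] - coords[hi]
                    # D-H...A angle: angle at H between H->D and H->A
                    v1 = coords[di] - coords[hi]
                    v2 = coords[ai] - coords[hi]
                    cosang = float(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    if angle >= angle_min:
                        ok = True
                        break
                if not ok:
                    continue
            count += 1
    return HBondCount(count=count, d_max=d_max, angle_min=angle_min if has_any_h else None)


@dataclass
class SecondaryStructureFractions:
    helix: np.ndarray
    sheet: np.ndarray
    coil: np.ndarray
    n_assignable: np.ndarray

    def to_tsv(self, times_ps: np.ndarray | None = None) -> str:
        lines = ["frame\ttime_ps\thelix\tsheet\tcoil"]
        for f in range(len(self.helix)):
            t = times_ps[f] if times_ps is not None else f
            lines.append(
                f"{f + 1}\t{t:g}\t{self.helix[f]:.6f}\t{self.sheet[f]:.6f}\t{self.coil[f]:.6f}"
            )
        return "\n".join(lines) + "\n"


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _classify(phi: float, psi: float) -> str:
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "helix"
    if -180.0 <= phi <= -80.0 and (80.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
        return "sheet"
    return "coil"


def secondary_structure_fractions(traj: Trajectory) -> SecondaryStructureFractions:
    """Helix/sheet/coil fractions per frame from φ/ψ dihedral boxes.

    Residues need backbone N, CA, C in themselves and their neighbours;
    terminal residues (undefined φ or ψ) are excluded from both numerator
    and denominator.  Fractions over assignable residues sum to 1.
    """
    top = traj.topology
    backbone: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(top.atoms):
        if a.name in ("N", "CA", "C"):
            if a.residue_key not in backbone:
                backbone[a.residue_key] = {}
                order.append(a.residue_key)
            backbone[a.residue_key][a.name] = i
    # interior residues with complete backbone plus complete neighbours on the same chain
    assignable: list[tuple[int, int, int, int, int]] = []  # Cprev, N, CA, C, Nnext
    for k in range(1, len(order) - 1):
        prev_key, key, next_key = order[k - 1], order[k], order[k + 1]
        if prev_key[0] != key[0] or next_key[0] != key[0]:
            continue
        if prev_key[1] != key[1] - 1 or next_key[1] != key[1] + 1:
            continue
        prev_b, b, next_b = backbone[prev_key], backbone[key], backbone[next_key]
        if "C" not in prev_b or not {"N", "CA", "C"} <= b.keys() or "N" not in next_b:
            continue
        assignable.append((prev_b["C"], b["N"], b["CA"], b["C"], next_b["N"]))
    F = traj.n_frames
    helix = np.zeros(F)
    sheet = np.zeros(F)
    coil = np.zeros(F)
    n_assignable = np.full(F, len(assignable))
    if not assignable:
        raise ValueError("no residues with complete backbone context for φ/ψ")
    for f in range(F):
        coords = traj.frames[f]
        counts = {"helix": 0, "sheet": 0, "coil": 0}
        for cprev, n, ca, c, nnext in assignable:
            phi = _dihedral(coords[cprev], coords[n], coords[ca], coords[c])
            psi = _dihedral(coords[n], coords[ca], coords[c], coords[nnext])
            counts[_classify(phi, psi)] += 1
        total = len(assignable)
        helix[f] = counts["helix"] / total
        sheet[f] = counts["sheet"] / total
        coil[f] = counts["coil"] / total
    return SecondaryStructureFractions(
        helix=helix, sheet=sheet, coil=coil, n_assignable=n_assignable
    )
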