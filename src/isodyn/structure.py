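"""Structures, trajectories and their plain-text formats.

The in-memory model is deliberately small: an ordered list of atom records
(:class:`AtomRecord`) with numpy coordinate views, a :class:`StructureModel`
wrapping one conformation, and a :class:`Trajectory` holding an ``(F, N, 3)``
coordinate array over a fixed topology.  Residues are numbered 1-based, the
way structural biologists quote them (K395, V76), and chains are single
letters.

Two text dialects are supported: multi-model PDB (``MODEL``/``ENDMDL`` with
fixed-column ``ATOM`` records) as the canonical interchange format, and a
whitespace XYZ-per-frame dialect (atom count header, then ``element x y z``
lines) convenient for synthetic data.  Binary trajectory formats are out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "TrajectoryParseError",
    "AnnotationError",
    "read_trajectory",
    "write_trajectory",
    "read_structure",
    "write_structure",
    "write_bfactor_annotation",
    "build_ideal_helix",
    "build_backbone_chain",
    "frame_count",
]


class TrajectoryParseError(ValueError):
    """Raised when trajectory text is malformed or internally inconsistent."""


class AnnotationError(ValueError):
    """Raised when a per-residue annotation cannot be written."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus a position in Å."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_index: int
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


class StructureModel:
    """An ordered collection of atoms forming one conformation.

    ``(chain_id, residue_index, name)`` must be unique across atoms.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) array of atom positions in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected {(len(self.atoms), 3)} coordinates, got {coords.shape}")
        return StructureModel(
            [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        )

    def select(
        self,
        chain: str | None = None,
        atom_name: str | None = None,
        residue_range: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria (inclusive range)."""
        idx = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain_id != chain:
                continue
            if atom_name is not None and a.name != atom_name:
                continue
            if residue_range is not None and not (
                residue_range[0] <= a.residue_index <= residue_range[1]
            ):
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residue_keys(self, atom_name: str = "CA") -> list[tuple[str, int]]:
        """Ordered (chain, residue_index) keys of residues bearing *atom_name*."""
        return [a.residue_key for a in self.atoms if a.name == atom_name]


@dataclass
class Trajectory:
    """F frames of coordinates over a fixed topology.

    ``topology`` carries the identities; its own coordinates are frame 0.
    ``capture_interval_ps`` is the time between stored snapshots.
    """

    topology: StructureModel
    frames: np.ndarray
    capture_interval_ps: float = 25.0
    name: str = "trajectory"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frames must be (F, {len(self.topology)}, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.capture_interval_ps <= 0:
            raise ValueError("capture_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        """Snapshot times; frame 0 sits at t = capture interval (t=0 not stored)."""
        return (np.arange(self.n_frames) + 1) * self.capture_interval_ps

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coordinates(self.frames[i])


# ---------------------------------------------------------------------------
# PDB fixed-column I/O (ATOM/HETATM, MODEL/ENDMDL)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, serial_fallback: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = serial_fallback
    name = line[12:16].strip()
    residue_name = line[17:20].strip() or "UNK"
    chain_id = line[21].strip() or "A"
    residue_index = int(line[22:26])
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_index=residue_index,
        element=element,
        position=np.array([x, y, z]),
    )


def _atom_signature(a: AtomRecord) -> tuple[str, int, str]:
    return (a.chain_id, a.residue_index, a.name)


def _read_pdb_trajectory(text: str, name: str, interval_ps: float) -> Trajectory:
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    model_labels: list[str] = []
    saw_model_record = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            current = []
            label = line[6:].strip() or str(len(models) + 1)
            model_labels.append(label)
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
                current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model_record and models:
                    raise TrajectoryParseError("ATOM record outside MODEL block")
                current = []
                model_labels.append(str(len(models) + 1))
            current.append(_parse_atom_line(line, len(current) + 1))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise TrajectoryParseError("no models with atoms found in input")

    ref_sig = [_atom_signature(a) for a in models[0]]
    coords = np.empty((len(models), len(ref_sig), 3))
    for m, atoms in enumerate(models):
        label = model_labels[m] if m < len(model_labels) else str(m + 1)
        if len(atoms) != len(ref_sig):
            raise TrajectoryParseError(
                f"MODEL {label}: expected {len(ref_sig)} atoms, found {len(atoms)}"
            )
        for i, a in enumerate(atoms):
            if _atom_signature(a) != ref_sig[i]:
                raise TrajectoryParseError(
                    f"MODEL {label}: atom {i + 1} is {_atom_signature(a)}, "
                    f"expected {ref_sig[i]}"
                )
            coords[m, i] = a.position
    topology = StructureModel(models[0])
    return Trajectory(topology, coords, capture_interval_ps=interval_ps, name=name)


def _read_xyz_trajectory(text: str, name: str, interval_ps: float) -> Trajectory:
    tokens_per_frame: list[list[tuple[str, float, float, float]]] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"expected atom-count header, got {lines[i]!r}"
            ) from exc
        block = lines[i + 1 : i + 1 + n]
        if len(block) != n:
            raise TrajectoryParseError(
                f"frame {len(tokens_per_frame) + 1}: expected {n} atom lines, "
                f"found {len(block)}"
            )
        frame = []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"malformed XYZ atom line: {ln!r}")
            frame.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        tokens_per_frame.append(frame)
        i += 1 + n
    if not tokens_per_frame:
        raise TrajectoryParseError("no frames found in XYZ input")
    n_atoms = len(tokens_per_frame[0])
    for f, frame in enumerate(tokens_per_frame):
        if len(frame) != n_atoms:
            raise TrajectoryParseError(
                f"frame {f + 1}: atom count {len(frame)} differs from frame 1 ({n_atoms})"
            )
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=el,
            residue_name="UNK",
            chain_id="A",
            residue_index=i + 1,
            element=el,
            position=np.array([x, y, z]),
        )
        for i, (el, x, y, z) in enumerate(tokens_per_frame[0])
    ]
    coords = np.array(
        [[[x, y, z] for (_, x, y, z) in frame] for frame in tokens_per_frame]
    )
    return Trajectory(StructureModel(atoms), coords, capture_interval_ps=interval_ps, name=name)


def read_trajectory(
    text: str, name: str = "trajectory", capture_interval_ps: float = 25.0
) -> Trajectory:
    """Parse a multi-model PDB or per-frame XYZ trajectory from text.

    The dialect is detected from the first non-blank line: PDB record names
    select the PDB path, a bare integer the XYZ path.
    """
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        first = stripped.split()[0]
        if first in ("MODEL", "ATOM", "HETATM", "REMARK", "HEADER", "TITLE", "CRYST1"):
            return _read_pdb_trajectory(text, name, capture_interval_ps)
        return _read_xyz_trajectory(text, name, capture_interval_ps)
    raise TrajectoryParseError("empty trajectory input")


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: 1-2 letter elements start at column 14; 4-char names fill 13-16
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _format_atom_line(a: AtomRecord, serial: int, bfactor: float = 0.0) -> str:
    x, y, z = a.position
    return (
        f"ATOM  {serial:5d} {_format_atom_name(a.name, a.element)} "
        f"{a.residue_name:>3s} {a.chain_id}{a.residue_index:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactor:6.2f}          "
        f"{a.element:>2s}"
    )


def write_structure(
    structure: StructureModel, bfactors: Sequence[float] | None = None
) -> str:
    lines = []
    for i, a in enumerate(structure.atoms):
        b = 0.0 if bfactors is None else bfactors[i]
        lines.append(_format_atom_line(a, i + 1, b))
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_structure(text: str) -> StructureModel:
    return read_trajectory(text).topology


def write_trajectory(traj: Trajectory) -> str:
    """Render a trajectory as multi-model PDB text (coordinates at 3 decimals)."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL {f + 1:8d}")
        for i, a in enumerate(traj.topology.atoms):
            moved = replace(a, position=traj.frames[f, i])
            lines.append(_format_atom_line(moved, i + 1))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_bfactor_annotation(
    structure: StructureModel,
    values: Mapping[tuple[str, int], float],
    fill_value: float | None = None,
) -> str:
    """Write PDB text with per-residue values stuffed into the B-factor column.

    Every residue must appear in *values* keyed by ``(chain_id, residue_index)``
    unless *fill_value* is given.  Values must fit the 6.2f column
    (−999.99 … 999.99).  This is how per-residue scalars (conservation
    categories, RMSF) are painted onto structures for any molecular viewer.
    """
    bfactors = []
    for a in structure.atoms:
        key = a.residue_key
        if key in values:
            v = float(values[key])
        elif fill_value is not None:
            v = float(fill_value)
        else:
            raise AnnotationError(
                f"no value for residue {key[0]}:{key[1]} and no fill value configured"
            )
        if not (-999.99 <= v <= 999.99):
            raise AnnotationError(
                f"value {v} for residue {key[0]}:{key[1]} does not fit the B-factor column"
            )
        bfactors.append(v)
    return write_structure(structure, bfactors)


# ---------------------------------------------------------------------------
# Toy structure builders
# ---------------------------------------------------------------------------

HELIX_RISE_PER_RESIDUE = 1.5      # Å
HELIX_TWIST_PER_RESIDUE = 100.0   # degrees
HELIX_RADIUS = 2.3                # Å


def build_ideal_helix(
    n_residues: int,
    chain_id: str = "A",
    residue_name: str = "ALA",
    start_index: int = 1,
) -> StructureModel:
    """Cα-only ideal α-helix: 1.5 Å rise and 100° twist per residue, radius 2.3 Å.

    Consecutive Cα–Cα distances are all equal (≈3.83 Å, the helix chord).
    """
    if n_residues < 1:
        raise ValueError(f"n_residues must be >= 1, got {n_residues}")
    atoms = []
    for i in range(n_residues):
        theta = math.radians(HELIX_TWIST_PER_RESIDUE * i)
        pos = np.array(
            [
                HELIX_RADIUS * math.cos(theta),
                HELIX_RADIUS * math.sin(theta),
                HELIX_RISE_PER_RESIDUE * i,
            ]
        )
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                residue_name=residue_name,
                chain_id=chain_id,
                residue_index=start_index + i,
                element="C",
                position=pos,
            )
        )
    return StructureModel(atoms)


# Standard backbone internal coordinates (Engh–Huber-like averages)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float
) -> np.ndarray:
    """Position of atom D given A-B-C, the C-D bond, B-C-D angle and A-B-C-D dihedral."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            -bond * math.sin(angle) * math.cos(dihedral),
            -bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone_chain(
    phi_psi: Sequence[tuple[float, float]],
    chain_id: str = "A",
    residue_name: str = "ALA",
) -> StructureModel:
    """N/CA/C backbone with prescribed (φ, ψ) per residue, ω fixed at 180°.

    The first residue's φ and the last residue's ψ are not realizable
    (no preceding C / following N) and are ignored; standard bond lengths
    and angles are used throughout.  Used to construct chains whose
    secondary-structure assignment is known by design.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("at least one residue required")
    coords: list[tuple[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.extend([("N", n0), ("CA", ca0), ("C", c0)])
    prev_n, prev_ca, prev_c = n0, ca0, c0
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        n_i = _place_atom(prev_n, prev_ca, prev_c, _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(prev_ca, prev_c, n_i, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_i = _place_atom(prev_c, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi_psi[i][0])
        coords.extend([("N", n_i), ("CA", ca_i), ("C", c_i)])
        prev_n, prev_ca, prev_c = n_i, ca_i, c_i
    atoms = []
    for j, (name, pos) in enumerate(coords):
        atoms.append(
            AtomRecord(
                serial=j + 1,
                name=name,
                residue_name=residue_name,
                chain_id=chain_id,
                residue_index=j // 3 + 1,
                element=name[0],
                position=pos,
            )
        )
    return StructureModel(atoms)


def frame_count(duration_ns: float, interval_ps: float) -> int:
    """Number of stored snapshots for a run of *duration_ns* at *interval_ps*.

    Convention: the t=0 structure is not counted and the endpoint is, so a
    650 ns run captured every 25 ps stores 26 000 snapshots.
    """
    if duration_ns <= 0 or interval_ps <= 0:
        raise ValueError("duration and interval must be positive")
    q = duration_ns * 1000.0 / interval_ps
    if abs(q - round(q)) > 1e-9:
        remainder = (duration_ns * 1000.0) % interval_ps
        raise ValueError(
            f"duration {duration_ns} ns is not a whole number of {interval_ps} ps "
            f"intervals (remainder {remainder:g} ps)"
        )
    return int(round(q))
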