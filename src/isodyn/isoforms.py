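"""Residue coordinate translation between splice isoforms.

Splice isoforms of one gene differ by insertion/deletion of whole exons'
worth of residues; literature positions quoted in one isoform's numbering
(e.g. K395 of SmgGDS-607) must be translated to the other's (K346 of
SmgGDS-558).  A mapping is an ordered list of non-overlapping edits stated
relative to the A→B direction; positions N-terminal of all edits map to
themselves, later positions shift by the cumulative signed edit length, and
positions inside a span absent from the target have no correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "IsoformEdit",
    "IsoformMapping",
    "NoCorrespondenceError",
    "map_position",
    "validate_mapping",
    "read_mapping_tsv",
    "write_mapping_tsv",
]


class NoCorrespondenceError(ValueError):
    """The queried position lies in a span absent from the target isoform."""

    def __init__(self, message: str, edit: "IsoformEdit"):
        super().__init__(message)
        self.edit = edit


@dataclass(frozen=True)
class IsoformEdit:
    """One insertion or deletion, stated relative to the A→B direction.

    For an insertion, ``start_in_A`` is the A-position *before which* the
    inserted residues appear in B (the insert occupies B positions
    ``map(start_in_A-1)+1 … +length``).  For a deletion, A positions
    ``start_in_A … start_in_A+length-1`` are absent from B.
    """

    kind: Literal["insertion", "deletion"]
    start_in_A: int
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"edit kind must be insertion or deletion, got {self.kind!r}")
        if self.start_in_A < 1:
            raise ValueError("start_in_A must be >= 1")
        if self.length < 1:
            raise ValueError("edit length must be >= 1")

    @property
    def end_in_A(self) -> int:
        """Last A position covered (insertions cover no A positions)."""
        return self.start_in_A + (self.length - 1 if self.kind == "deletion" else -1)


@dataclass(frozen=True)
class IsoformMapping:
    name_A: str
    name_B: str
    length_A: int
    length_B: int
    edits: tuple[IsoformEdit, ...]

    def __init__(
        self,
        name_A: str,
        name_B: str,
        length_A: int,
        length_B: int,
        edits: Iterable[IsoformEdit],
    ):
        object.__setattr__(self, "name_A", name_A)
        object.__setattr__(self, "name_B", name_B)
        object.__setattr__(self, "length_A", int(length_A))
        object.__setattr__(self, "length_B", int(length_B))
        object.__setattr__(self, "edits", tuple(edits))

    def inverted(self) -> "IsoformMapping":
        """The B→A mapping (insertions become deletions and vice versa)."""
        inverse = []
        offset = 0
        for e in self.edits:
            start_in_B = e.start_in_A + offset
            if e.kind == "insertion":
                inverse.append(IsoformEdit("deletion", start_in_B, e.length))
                offset += e.length
            else:
                inverse.append(IsoformEdit("insertion", start_in_B, e.length))
                offset -= e.length
        return IsoformMapping(self.name_B, self.name_A, self.length_B, self.length_A, inverse)


def validate_mapping(mapping: IsoformMapping) -> tuple[bool, list[str]]:
    """Check length bookkeeping and edit ordering; returns (ok, diagnostics)."""
    diagnostics: list[str] = []
    if mapping.length_A < 1 or mapping.length_B < 1:
        diagnostics.append("isoform lengths must be positive")
    net = sum(e.length if e.kind == "insertion" else -e.length for e in mapping.edits)
    if mapping.length_A + net != mapping.length_B:
        diagnostics.append(
            f"length mismatch: {mapping.length_A} + net edit {net:+d} = "
            f"{mapping.length_A + net}, expected length_B = {mapping.length_B}"
        )
    prev_end = 0
    for e in mapping.edits:
        if e.start_in_A <= prev_end:
            diagnostics.append(
                f"edits overlap or are unsorted near A position {e.start_in_A}"
            )
        prev_end = max(prev_end, e.end_in_A if e.kind == "deletion" else e.start_in_A - 1)
        if e.kind == "deletion" and e.end_in_A > mapping.length_A:
            diagnostics.append(
                f"deletion {e.start_in_A}+{e.length} extends past length_A {mapping.length_A}"
            )
        if e.kind == "insertion" and e.start_in_A > mapping.length_A + 1:
            diagnostics.append(
                f"insertion point {e.start_in_A} lies past length_A {mapping.length_A}"
            )
    return (not diagnostics, diagnostics)


def map_position(
    pos: int,
    mapping: IsoformMapping,
    direction: Literal["A_to_B", "B_to_A"] = "A_to_B",
) -> int:
    """Translate a 1-based residue position between isoforms.

    Raises :class:`NoCorrespondenceError` when the position lies inside a
    span that the target isoform lacks, and ``ValueError`` when out of range.
    """
    if direction == "B_to_A":
        return map_position(pos, mapping.inverted(), "A_to_B")
    if direction != "A_to_B":
        raise ValueError(f"direction must be A_to_B or B_to_A, got {direction!r}")
    if not (1 <= pos <= mapping.length_A):
        raise ValueError(
            f"position {pos} out of range 1..{mapping.length_A} for {mapping.name_A}"
        )
    offset = 0
    for e in mapping.edits:
        if e.kind == "insertion":
            if pos >= e.start_in_A:
                offset += e.length
        else:
            if pos > e.end_in_A:
                offset -= e.length
            elif pos >= e.start_in_A:
                raise NoCorrespondenceError(
                    f"{mapping.name_A} position {pos} lies in the "
                    f"{e.length}-residue span ({e.start_in_A}-{e.end_in_A}) "
                    f"absent from {mapping.name_B}",
                    e,
                )
    return pos + offset


# ---------------------------------------------------------------------------
# TSV interchange: header line "#A name_A length_A", "#B name_B length_B",
# then columns kind<TAB>start_in_A<TAB>length.
# ---------------------------------------------------------------------------

def write_mapping_tsv(mapping: IsoformMapping) -> str:
    lines = [
        f"#A\t{mapping.name_A}\t{mapping.length_A}",
        f"#B\t{mapping.name_B}\t{mapping.length_B}",
        "kind\tstart_in_A\tlength",
    ]
    for e in mapping.edits:
        lines.append(f"{e.kind}\t{e.start_in_A}\t{e.length}")
    return "\n".join(lines) + "\n"


def read_mapping_tsv(text: str) -> IsoformMapping:
    name_A = name_B = None
    length_A = length_B = None
    edits: list[IsoformEdit] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if parts[0] == "#A":
            name_A, length_A = parts[1], int(parts[2])
        elif parts[0] == "#B":
            name_B, length_B = parts[1], int(parts[2])
        elif parts[0] == "kind":
            continue
        else:
            edits.append(IsoformEdit(parts[0], int(parts[1]), int(parts[2])))
    if name_A is None or name_B is None:
        raise ValueError("mapping TSV missing #A/#B header lines")
    return IsoformMapping(name_A, name_B, length_A, length_B, edits)
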