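"""Per-position evolutionary conservation from a protein MSA.

Conservation is scored relative to a named reference row (the human sequence
whose structure is being painted), not a column consensus: for each alignment
column where the reference is not gapped, the match fraction is the share of
non-gap rows carrying the reference residue.  Display categories follow the
conventional strict (100 %) / high (>90 %) colouring; columns gapped in a
majority of rows are flagged rather than scored, which keeps fragmentary
ortholog sequences from diluting the profile.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Msa",
    "ColumnConservation",
    "ConservationProfile",
    "parse_alignment",
    "column_match_fractions",
    "assign_categories",
    "profile_to_tsv",
    "category_bfactors",
]

GAP = "-"

#: Default per-category values used when painting a profile onto a structure.
DEFAULT_CATEGORY_VALUES: Mapping[str, float] = {
    "strict": 1.00,
    "high": 0.90,
    "variable": 0.50,
    "gap": 0.00,
}


@dataclass(frozen=True)
class Msa:
    """An aligned set of protein sequences with a designated reference row."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least two rows")
        width = len(self.rows[0])
        for i, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {i!r} has length {len(row)}, expected {width}"
                )
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not among sequence ids")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]


@dataclass
class ColumnConservation:
    column_index: int
    reference_position: int
    reference_residue: str
    match_fraction: float
    n_effective: int
    category: str | None = None


@dataclass
class ConservationProfile:
    """Per-reference-position conservation, one entry per ungapped reference residue."""

    reference_id: str
    n_rows: int
    columns: list[ColumnConservation] = field(default_factory=list)

    def __iter__(self):
        return iter(self.columns)

    def __len__(self) -> int:
        return len(self.columns)


def parse_alignment(text: str, reference_id: str | None = None) -> Msa:
    """Parse aligned FASTA text; rows are upper-cased, '.' gaps normalized to '-'.

    The reference defaults to the first record.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) < 2:
        raise ValueError("alignment must contain at least two sequences")
    ids = []
    rows = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", GAP))
    width = len(rows[0])
    for i, row in zip(ids, rows):
        if len(row) != width:
            raise ValueError(
                f"ragged alignment: sequence {i!r} has aligned length {len(row)}, "
                f"expected {width}"
            )
    return Msa(tuple(ids), tuple(rows), reference_id or ids[0])


def column_match_fractions(msa: Msa) -> ConservationProfile:
    """Score every non-reference-gap column against the reference residue.

    ``n_effective`` counts non-gap rows (the reference always among them);
    the match fraction is matches / n_effective, so the reference row itself
    always counts as one match.
    """
    ref = msa.reference_row
    profile = ConservationProfile(reference_id=msa.reference_id, n_rows=msa.n_rows)
    ref_pos = 0
    for col in range(msa.n_columns):
        ref_sym = ref[col]
        if ref_sym == GAP:
            continue
        ref_pos += 1
        symbols = [row[col] for row in msa.rows]
        non_gap = [s for s in symbols if s != GAP]
        matches = sum(1 for s in non_gap if s == ref_sym)
        profile.columns.append(
            ColumnConservation(
                column_index=col,
                reference_position=ref_pos,
                reference_residue=ref_sym,
                match_fraction=matches / len(non_gap),
                n_effective=len(non_gap),
            )
        )
    return profile


def assign_categories(
    profile: ConservationProfile,
    strict_threshold: float = 1.0,
    high_threshold: float = 0.9,
    gap_majority: float = 0.5,
) -> ConservationProfile:
    """Assign display categories in place and return the profile.

    gap: the column is gapped in more than *gap_majority* of rows;
    strict: every non-gap row matches (fraction == strict_threshold, default 1.0);
    high: fraction strictly greater than *high_threshold* (default 0.9 — a
    column at exactly 0.9 is "variable");
    variable: everything else.
    """
    if not (0.0 <= high_threshold < strict_threshold <= 1.0):
        raise ValueError(
            f"thresholds must satisfy 0 <= high ({high_threshold}) < "
            f"strict ({strict_threshold}) <= 1"
        )
    for col in profile.columns:
        gap_fraction = 1.0 - col.n_effective / profile.n_rows
        if gap_fraction > gap_majority:
            col.category = "gap"
        elif col.match_fraction >= strict_threshold:
            col.category = "strict"
        elif col.match_fraction > high_threshold:
            col.category = "high"
        else:
            col.category = "variable"
    return profile


def profile_to_tsv(profile: ConservationProfile) -> str:
    lines = ["reference_position\treference_residue\tmatch_fraction\tn_effective\tcategory"]
    for col in profile.columns:
        lines.append(
            f"{col.reference_position}\t{col.reference_residue}\t"
            f"{col.match_fraction:.6g}\t{col.n_effective}\t{col.category or ''}"
        )
    return "\n".join(lines) + "\n"


def category_bfactors(
    profile: ConservationProfile,
    chain_id: str,
    category_values: Mapping[str, float] = DEFAULT_CATEGORY_VALUES,
) -> dict[tuple[str, int], float]:
    """Per-residue values for B-factor painting of a categorized profile."""
    out: dict[tuple[str, int], float] = {}
    for col in profile.columns:
        if col.category is None:
            raise ValueError("profile has no categories; call assign_categories first")
        out[(chain_id, col.reference_position)] = category_values[col.category]
    return out
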