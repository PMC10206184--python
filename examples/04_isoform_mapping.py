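"""Translate residue positions between splice isoforms.

The fixture ships two mappings: the GTPase pair (192-residue canonical
isoform vs the 211-residue variant with a 19-residue loop inserted at
position 75) and the chaperone pair (607- vs 558-residue isoforms differing
by one 49-residue armadillo domain).  Positions N-terminal of an edit map to
themselves; downstream positions shift by the cumulative edit length; and
residues inside a spliced-out span have no correspondence at all.
"""

from isodyn import map_position, validate_mapping
from isodyn.isoforms import NoCorrespondenceError
from isodyn.synthetic import two_chain_fixture

fixture = two_chain_fixture(n_frames=2)

for mapping in fixture.mappings.values():
    ok, _ = validate_mapping(mapping)
    print(f"{mapping.name_A} ({mapping.length_A} aa) -> "
          f"{mapping.name_B} ({mapping.length_B} aa): bookkeeping ok = {ok}")

smg = fixture.mappings["SMGGDS_607_558"]
for pos in (324, 328, 395):
    print(f"  {smg.name_A} {pos:>3d}  ->  {smg.name_B} {map_position(pos, smg)}")

rac = fixture.mappings["RAC1_RAC1B"]
print(f"  {rac.name_A}  75  ->  {rac.name_B} {map_position(75, rac)} "
      "(pushed past the 19-residue insert)")
try:
    map_position(80, rac, "B_to_A")
except NoCorrespondenceError as err:
    print(f"  {rac.name_B}  80  ->  {err}")
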