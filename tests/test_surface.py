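import math

import numpy as np
import pytest

from isodyn.structure import AtomRecord, StructureModel, Trajectory, build_backbone_chain
from isodyn.surface import (
    count_hbonds,
    secondary_structure_fractions,
    shrake_rupley_sasa,
)


def _atom(serial, element, position, name=None, chain="A", resi=None):
    return AtomRecord(serial, name or element, "UNK", chain,
                      resi or serial, element, np.asarray(position, float))


class TestSasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        model = StructureModel([_atom(1, "C", [0, 0, 0])])
        result = shrake_rupley_sasa(model)
        analytic = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(analytic, rel=0.01)

    def test_distant_atoms_are_additive(self):
        one = shrake_rupley_sasa(StructureModel([_atom(1, "C", [0, 0, 0])])).total
        two = shrake_rupley_sasa(StructureModel([
            _atom(1, "C", [0, 0, 0]), _atom(2, "C", [100, 0, 0])])).total
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_fully_buried_atom_has_zero_area(self):
        # hydrogen (r 1.20) at the centre of a sulfur (r 1.80) sphere:
        # 0 + 1.20 + 1.4 < 1.80 + 1.4 fails, so use a tighter geometry where
        # every test point of the small sphere lies inside the big one.
        model = StructureModel([
            _atom(1, "H", [0.0, 0.0, 0.0]),
            _atom(2, "S", [0.5, 0.0, 0.0]),
        ])
        result = shrake_rupley_sasa(model)
        # points of H sphere lie within 0.5+2.6=3.1 < 3.2 of the S centre
        assert result.per_atom[0] == pytest.approx(0.0, abs=1e-12)

    def test_adding_an_atom_never_increases_existing_sasa(self):
        rng = np.random.default_rng(12)
        atoms = [_atom(i + 1, "C", rng.uniform(0, 6, 3)) for i in range(6)]
        before = shrake_rupley_sasa(StructureModel(atoms)).per_atom
        extra = atoms + [_atom(7, "O", [3.0, 3.0, 3.0])]
        after = shrake_rupley_sasa(StructureModel(extra)).per_atom[:6]
        assert np.all(after <= before + 1e-9)

    def test_translation_invariance_is_exact(self):
        rng = np.random.default_rng(13)
        coords = rng.uniform(0, 8, (5, 3))
        atoms = [_atom(i + 1, "N", c) for i, c in enumerate(coords)]
        base = shrake_rupley_sasa(StructureModel(atoms))
        moved = [_atom(i + 1, "N", c + [10, -4, 2]) for i, c in enumerate(coords)]
        shifted = shrake_rupley_sasa(StructureModel(moved))
        assert np.allclose(shifted.per_atom, base.per_atom, atol=1e-9)

    def test_rotation_invariance_to_quadrature_accuracy(self):
        # test points are fixed in space, so rotating the molecule re-rolls
        # which points are occluded: agreement is quadrature-limited, not exact
        rng = np.random.default_rng(13)
        coords = rng.uniform(0, 8, (5, 3))
        atoms = [_atom(i + 1, "N", c) for i, c in enumerate(coords)]
        base = shrake_rupley_sasa(StructureModel(atoms))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = [_atom(i + 1, "N", c @ R.T) for i, c in enumerate(coords)]
        rotated = shrake_rupley_sasa(StructureModel(moved))
        assert rotated.total == pytest.approx(base.total, rel=5e-3)

    def test_quadrature_convergence(self):
        model = StructureModel([_atom(1, "C", [0, 0, 0]), _atom(2, "C", [2.5, 0, 0])])
        coarse = shrake_rupley_sasa(model, n_points=960).total
        fine = shrake_rupley_sasa(model, n_points=1920).total
        assert abs(fine - coarse) / fine < 0.005

    def test_total_equals_sum_of_atoms_and_residues(self):
        rng = np.random.default_rng(14)
        atoms = [_atom(i + 1, "C", rng.uniform(0, 5, 3)) for i in range(4)]
        result = shrake_rupley_sasa(StructureModel(atoms))
        assert result.total == pytest.approx(result.per_atom.sum(), abs=1e-6)
        assert result.total == pytest.approx(sum(result.per_residue.values()), abs=1e-6)

    def test_unknown_element_requires_explicit_default(self):
        model = StructureModel([_atom(1, "ZZ", [0, 0, 0])])
        with pytest.raises(ValueError, match="ZZ"):
            shrake_rupley_sasa(model)
        assert shrake_rupley_sasa(model, allow_default_radius=True).total > 0


class TestHbonds:
    def test_pair_within_cutoff_counts(self):
        model = StructureModel([_atom(1, "O", [0, 0, 0]), _atom(2, "O", [2.8, 0, 0])])
        assert count_hbonds(model, [0], [1]).count == 1

    def test_pair_beyond_cutoff_does_not(self):
        model = StructureModel([_atom(1, "O", [0, 0, 0]), _atom(2, "O", [4.0, 0, 0])])
        assert count_hbonds(model, [0], [1]).count == 0

    def test_one_donor_two_acceptors(self):
        model = StructureModel([
            _atom(1, "O", [0, 0, 0]),
            _atom(2, "O", [2.8, 0, 0]),
            _atom(3, "N", [0, 2.8, 0]),
        ])
        assert count_hbonds(model, [0], [1, 2]).count == 2

    def test_same_residue_pairs_excluded(self):
        model = StructureModel([
            _atom(1, "O", [0, 0, 0], name="O1", resi=1),
            _atom(2, "O", [2.5, 0, 0], name="O2", resi=1),
        ])
        assert count_hbonds(model, [0], [1]).count == 0

    def test_angle_criterion_applies_when_hydrogens_present(self):
        # donor H points away from the acceptor: D-H...A angle ~0, bond rejected
        model = StructureModel([
            _atom(1, "O", [0, 0, 0], resi=1),
            _atom(2, "H", [-0.96, 0, 0], resi=1),
            _atom(3, "O", [2.8, 0, 0], resi=2),
        ])
        assert count_hbonds(model, [0], [2]).count == 0
        # donor H points toward the acceptor: angle ~180, accepted
        toward = StructureModel([
            _atom(1, "O", [0, 0, 0], resi=1),
            _atom(2, "H", [0.96, 0, 0], resi=1),
            _atom(3, "O", [2.8, 0, 0], resi=2),
        ])
        assert count_hbonds(toward, [0], [2]).count == 1

    def test_empty_selection_rejected(self):
        model = StructureModel([_atom(1, "O", [0, 0, 0])])
        with pytest.raises(ValueError, match="non-empty"):
            count_hbonds(model, [], [0])


class TestSecondaryStructure:
    def _single_frame(self, model):
        return Trajectory(model, model.coordinates[None])

    def test_canonical_helix_dihedrals_classified_helix(self):
        chain = build_backbone_chain([(-57.0, -47.0)] * 10)
        ss = secondary_structure_fractions(self._single_frame(chain))
        assert ss.helix[0] == pytest.approx(1.0)

    def test_extended_chain_classified_sheet(self):
        chain = build_backbone_chain([(-120.0, 120.0)] * 10)
        ss = secondary_structure_fractions(self._single_frame(chain))
        assert ss.sheet[0] == pytest.approx(1.0)

    def test_left_handed_region_classified_coil(self):
        chain = build_backbone_chain([(60.0, 60.0)] * 10)
        ss = secondary_structure_fractions(self._single_frame(chain))
        assert ss.coil[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        chain = build_backbone_chain([(-57.0, -47.0)] * 5 + [(-120.0, 120.0)] * 5)
        ss = secondary_structure_fractions(self._single_frame(chain))
        assert ss.helix[0] + ss.sheet[0] + ss.coil[0] == pytest.approx(1.0, abs=1e-9)

    def test_rigid_transform_invariance(self):
        chain = build_backbone_chain([(-57.0, -47.0)] * 8)
        coords = chain.coordinates
        theta = 1.1
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        moved = chain.with_coordinates(coords @ R.T + [5, 5, 5])
        a = secondary_structure_fractions(self._single_frame(chain))
        b = secondary_structure_fractions(self._single_frame(moved))
        assert a.helix[0] == pytest.approx(b.helix[0], abs=1e-9)

    def test_ca_only_model_rejected(self):
        from isodyn.structure import build_ideal_helix

        ca_only = build_ideal_helix(6)
        with pytest.raises(ValueError, match="backbone"):
            secondary_structure_fractions(self._single_frame(ca_only))
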