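import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isodyn.dynamics import (
    AnalysisConfig,
    Dccm,
    DegenerateGeometryError,
    RegionDefinition,
    RegionScore,
    RmsfProfile,
    align_trajectory,
    compute_dccm,
    equilibrium_diagnostics,
    extract_correlated_pairs,
    kabsch_superpose,
    percent_total_movement,
    rank_conformers,
    region_movement_score,
    rmsd_series,
    rmsf_profile,
)
from isodyn.structure import Trajectory, build_ideal_helix
from oracles import brute_force_rmsd

RAW = AnalysisConfig(align=False)


def _rotz(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered_exactly(self):
        pts = np.random.default_rng(1).normal(size=(7, 3))
        mobile = pts @ _rotz(90).T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(mobile, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.apply(mobile), pts, atol=1e-9)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(2)
        res = kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_small_triangle_matches_brute_force_frozen_value(self):
        # independent rotation-space search gives 0.08876547238018946
        mobile = np.array([[0, 0, 0], [1, 0, 0], [0, 1.2, 0]], float)
        reference = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        res = kabsch_superpose(mobile, reference)
        assert res.rmsd == pytest.approx(0.08876547238018946, abs=1e-9)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            P, Q = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                brute_force_rmsd(P, Q), abs=1e-5)

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_count_mismatch_and_too_few_points(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAlignTrajectory:
    def test_rigidly_moved_frames_collapse_to_one_structure(self):
        base = build_ideal_helix(20)
        frames = np.stack([
            base.coordinates,
            base.coordinates @ _rotz(45).T + [3, 0, 0],
            base.coordinates @ _rotz(-30).T + [0, 5, -2],
        ])
        aligned = align_trajectory(Trajectory(base, frames))
        assert np.allclose(aligned.frames[0], aligned.frames[1], atol=1e-6)
        assert np.allclose(aligned.frames[0], aligned.frames[2], atol=1e-6)

    def test_idempotence(self, small_gaussian_trajectory):
        once = align_trajectory(small_gaussian_trajectory)
        twice = align_trajectory(once)
        assert np.allclose(once.frames, twice.frames, atol=1e-9)

    def test_empty_selection_rejected(self, small_gaussian_trajectory):
        config = AnalysisConfig(selection_atom_name="CB")
        with pytest.raises(ValueError, match="selection"):
            align_trajectory(small_gaussian_trajectory, config)


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self):
        base = build_ideal_helix(10)
        traj = Trajectory(base, np.repeat(base.coordinates[None], 4, axis=0))
        series = rmsd_series(traj)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_single_displaced_atom_raw_mode(self):
        n = 16
        base = build_ideal_helix(n)
        frames = np.repeat(base.coordinates[None], 2, axis=0)
        frames[1, 3, 0] += 3.0
        series = rmsd_series(Trajectory(base, frames),
                            AnalysisConfig(align=False, reference="first"))
        assert series.values[0] == pytest.approx(0.0)
        assert series.values[1] == pytest.approx(3.0 / np.sqrt(n))

    def test_times_start_at_capture_interval(self, small_gaussian_trajectory):
        series = rmsd_series(small_gaussian_trajectory, RAW)
        assert series.times_ps[0] == pytest.approx(25.0)
        assert np.all(np.diff(series.times_ps) == pytest.approx(25.0))


class TestRmsfProfile:
    def test_constant_trajectory_is_zero(self):
        base = build_ideal_helix(8)
        traj = Trajectory(base, np.repeat(base.coordinates[None], 3, axis=0))
        profile = rmsf_profile(traj, RAW)
        assert np.allclose(profile.values, 0.0, atol=1e-12)

    def test_two_frame_symmetric_displacement_forced_by_definition(self):
        base = build_ideal_helix(5)
        d = 0.7
        frames = np.repeat(base.coordinates[None], 2, axis=0)
        frames[0, 2, 0] += d
        frames[1, 2, 0] -= d
        profile = rmsf_profile(Trajectory(base, frames), RAW)
        assert profile.values[2] == pytest.approx(d)
        assert profile.values[0] == pytest.approx(0.0)

    def test_single_frame_rejected(self):
        base = build_ideal_helix(5)
        with pytest.raises(ValueError, match="frames"):
            rmsf_profile(Trajectory(base, base.coordinates[None]), RAW)


def _profile(name, values, chain="A"):
    keys = [(chain, i + 1) for i in range(len(values))]
    return RmsfProfile(name, keys, np.asarray(values, float))


class TestPercentTable:
    def test_equal_profiles_split_evenly(self):
        profiles = [_profile(c, [1.0, 2.0]) for c in "abcd"]
        table = percent_total_movement(profiles)
        assert np.allclose(table.to_numpy(dtype=float), 25.0)

    def test_two_to_one_ratio(self):
        table = percent_total_movement(
            [_profile("a", [2.0]), _profile("b", [1.0]), _profile("c", [1.0])])
        assert table.loc[("A", 1)].tolist() == pytest.approx([50.0, 25.0, 25.0])

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(4)
        profiles = [_profile(c, rng.uniform(0.1, 2.0, 7)) for c in "abc"]
        table = percent_total_movement(profiles)
        assert np.allclose(table.sum(axis=1).to_numpy(dtype=float), 100.0, atol=1e-6)

    def test_all_zero_residue_marked_undefined(self):
        table = percent_total_movement(
            [_profile("a", [0.0, 1.0]), _profile("b", [0.0, 3.0])])
        assert table.loc[("A", 1)].isna().all()
        assert table.loc[("A", 2)].notna().all()

    def test_mismatched_residues_listed(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            percent_total_movement([_profile("a", [1.0]), _profile("b", [1.0, 2.0])])


class TestRegionsAndRanking:
    def test_region_score_is_summed_rmsf(self):
        profile = _profile("a", [1.0, 2.0, 3.0])
        region = RegionDefinition("r", "A", ((1, 3),))
        assert region_movement_score(profile, region).score == pytest.approx(6.0)

    def test_missing_residue_named(self):
        profile = _profile("a", [1.0])
        region = RegionDefinition("r", "A", ((1, 2),))
        with pytest.raises(ValueError, match="A:2"):
            region_movement_score(profile, region)

    def test_partition_additivity(self):
        profile = _profile("a", [1.0, 2.0, 3.0, 4.0])
        whole = region_movement_score(profile, RegionDefinition("w", "A", ((1, 4),)))
        left = region_movement_score(profile, RegionDefinition("l", "A", ((1, 2),)))
        right = region_movement_score(profile, RegionDefinition("r", "A", ((3, 4),)))
        assert left.score + right.score == pytest.approx(whole.score)

    def test_ranking_ascending(self):
        scores = [RegionScore("A", "PBR", 4.0), RegionScore("B", "PBR", 6.0),
                  RegionScore("C", "PBR", 5.0)]
        assert rank_conformers(scores, "PBR") == ["A", "C", "B"]

    def test_tie_breaks_lexicographically(self):
        scores = [RegionScore("B", "PBR", 4.0), RegionScore("A", "PBR", 4.0)]
        assert rank_conformers(scores, "PBR") == ["A", "B"]

    def test_single_conformer(self):
        assert rank_conformers([RegionScore("only", "PBR", 1.0)], "PBR") == ["only"]

    def test_missing_score_rejected(self):
        scores = [RegionScore("A", "PBR", 4.0), RegionScore("B", "loop", 1.0)]
        with pytest.raises(ValueError, match="'B'"):
            rank_conformers(scores, "PBR")

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_ranking_is_permutation_and_stable_under_reordering(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"c{i}" for i in range(int(rng.integers(2, 7)))]
        scores = [RegionScore(n, "PBR", float(rng.integers(0, 3))) for n in names]
        ranked = rank_conformers(scores, "PBR")
        assert sorted(ranked) == sorted(names)
        shuffled = [scores[i] for i in rng.permutation(len(scores))]
        assert rank_conformers(shuffled, "PBR") == ranked


class TestDccm:
    def _traj_from_displacements(self, disp):
        """disp: (F, N) scalar displacement along x per residue."""
        F, n = disp.shape
        base = build_ideal_helix(n)
        frames = np.repeat(base.coordinates[None], F, axis=0)
        frames[:, :, 0] += disp
        return Trajectory(base, frames)

    def test_identical_series_give_plus_one(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(50, 1))
        disp = np.hstack([z, z, rng.normal(size=(50, 1))])
        dccm = compute_dccm(self._traj_from_displacements(disp), RAW)
        assert dccm.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_series_give_minus_one(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(50, 1))
        disp = np.hstack([z, -z, rng.normal(size=(50, 1))])
        dccm = compute_dccm(self._traj_from_displacements(disp), RAW)
        assert dccm.matrix[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_matrix_invariants(self, small_gaussian_trajectory):
        dccm = compute_dccm(small_gaussian_trajectory)
        assert np.allclose(dccm.matrix, dccm.matrix.T, atol=1e-12)
        assert np.allclose(np.diag(dccm.matrix), 1.0, atol=1e-9)
        assert np.nanmax(np.abs(dccm.matrix)) <= 1.0 + 1e-9

    def test_zero_variance_residue_marked_undefined(self):
        rng = np.random.default_rng(7)
        disp = rng.normal(size=(40, 4))
        disp[:, 2] = 0.0
        base = build_ideal_helix(4)
        frames = np.repeat(base.coordinates[None], 40, axis=0)
        frames[:, :, 0] += disp
        dccm = compute_dccm(Trajectory(base, frames), RAW)
        assert ("A", 3) in dccm.undefined
        assert np.isnan(dccm.matrix[2, 0])
        assert not np.isnan(dccm.matrix[0, 1])

    def test_frame_shuffle_invariance(self, small_gaussian_trajectory):
        dccm = compute_dccm(small_gaussian_trajectory, RAW)
        rng = np.random.default_rng(8)
        shuffled = Trajectory(
            small_gaussian_trajectory.topology,
            small_gaussian_trajectory.frames[rng.permutation(
                small_gaussian_trajectory.n_frames)],
        )
        dccm2 = compute_dccm(shuffled, RAW)
        assert np.allclose(dccm.matrix, dccm2.matrix, atol=1e-9)

    def test_too_few_frames_rejected(self):
        base = build_ideal_helix(4)
        with pytest.raises(ValueError, match=">= 3"):
            compute_dccm(Trajectory(base, np.repeat(base.coordinates[None], 2, 0)), RAW)


def _toy_dccm():
    keys = [("A", 76), ("A", 80), ("B", 197)]
    names = {("A", 76): "VAL", ("A", 80): "ALA", ("B", 197): "GLU"}
    m = np.eye(3)
    m[0, 2] = m[2, 0] = 0.7
    m[0, 1] = m[1, 0] = -0.6
    return Dccm(residue_keys=keys, matrix=m, residue_names=names)


class TestPairExtraction:
    def test_single_interchain_pair_with_literature_notation(self):
        pairs = extract_correlated_pairs(_toy_dccm(), AnalysisConfig())
        assert len(pairs) == 1
        assert pairs[0].pair_class == "inter_chain"
        assert pairs[0].label == "V76-E197"
        assert pairs[0].correlation == pytest.approx(0.7)

    def test_absolute_mode_picks_up_negative_couplings(self):
        pairs = extract_correlated_pairs(
            _toy_dccm(), AnalysisConfig(threshold_mode="absolute"))
        assert {p.label for p in pairs} == {"V76-A80", "V76-E197"}

    def test_threshold_one_gives_empty_list(self):
        assert extract_correlated_pairs(_toy_dccm(), AnalysisConfig(dccm_threshold=1.0)) == []

    def test_interchain_scope_filters_same_chain(self):
        pairs = extract_correlated_pairs(
            _toy_dccm(), AnalysisConfig(threshold_mode="absolute"), scope="inter_chain")
        assert [p.label for p in pairs] == ["V76-E197"]

    def test_region_pair_scope_requires_disjoint_same_chain_regions(self):
        overlapping = (RegionDefinition("a", "A", ((70, 80),)),
                       RegionDefinition("b", "A", ((75, 85),)))
        with pytest.raises(ValueError, match="overlap"):
            extract_correlated_pairs(_toy_dccm(), AnalysisConfig(),
                                     scope="intra_pair_of_regions", regions=overlapping)


class TestEquilibriumDiagnostics:
    def test_constant_series_plateaus(self):
        report = equilibrium_diagnostics({"energy": np.full(100, 7.0)})
        assert report.series[0].plateau is True

    def test_steep_linear_series_does_not_plateau(self):
        report = equilibrium_diagnostics({"drift": np.arange(100, dtype=float)})
        assert report.series[0].plateau is False

    def test_relaxing_series_plateaus_only_when_complete(self):
        rng = np.random.default_rng(9)
        t = np.arange(2000, dtype=float)
        series = 5.0 + 20.0 * np.exp(-t / 150.0) + rng.normal(0, 0.5, t.size)
        full = equilibrium_diagnostics({"sasa": series})
        early = equilibrium_diagnostics({"sasa": series[:400]})
        assert full.series[0].plateau is True
        assert early.series[0].plateau is False

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="points"):
            equilibrium_diagnostics({"x": np.arange(5, dtype=float)})


class TestRigidMotionInvariance:
    def test_aligned_statistics_survive_rigid_contamination(self, small_gaussian_trajectory):
        from isodyn.synthetic import inject_rigid_body_motion

        clean_rmsf = rmsf_profile(small_gaussian_trajectory)
        dirty = inject_rigid_body_motion(small_gaussian_trajectory, seed=11)
        dirty_rmsf = rmsf_profile(dirty)
        rel = np.abs(dirty_rmsf.values - clean_rmsf.values) / clean_rmsf.values
        assert rel.max() < 0.02
        clean_dccm = compute_dccm(small_gaussian_trajectory)
        dirty_dccm = compute_dccm(dirty)
        assert np.nanmax(np.abs(clean_dccm.matrix - dirty_dccm.matrix)) < 0.02
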