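"""Binding-event detection, bound fractions, geometry, density, clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from grxtools.trajectory import (
    TrajectoryReplicate, GsTrajectory, detect_bound, binding_events,
    fraction_bound, FractionBoundResult, welch_ttest, sss_geometry,
    occupation_density, linearize_path, kabsch_rmsd, cluster_poses,
)

DIS = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])  # midpoint (1,0,0)


def single_frame(gs_positions):
    gs = np.asarray(gs_positions, dtype=float)[None, :, :]
    return TrajectoryReplicate(gs_xyz=gs, disulfide_xyz=DIS[None])


class TestDetectBound:
    @pytest.mark.parametrize("x,expected", [
        (6.4, True),    # 5.4 A from the midpoint
        (6.6, False),   # 5.6 A
        (6.5, True),    # exactly 5.5 A: boundary inclusive
    ])
    def test_distance_boundary(self, x, expected):
        events = detect_bound(np.array([[x, 0.0, 0.0]]), DIS)
        assert bool(events) is expected

    def test_distance_is_to_midpoint(self):
        events = detect_bound(np.array([[1.0, 3.0, 0.0]]), DIS)
        assert events[0].s_s_distance == pytest.approx(3.0)

    @given(angle=st.floats(0, 2 * np.pi), axis=st.integers(0, 2),
           shift=st.floats(-50, 50))
    def test_invariant_under_rigid_transforms(self, angle, axis, shift):
        gs = np.array([[4.0, 2.0, 1.0], [9.0, 0.0, 0.0]])
        rotvec = np.zeros(3)
        rotvec[axis] = angle
        rot = Rotation.from_rotvec(rotvec)
        t = np.full(3, shift)
        events_a = detect_bound(gs, DIS)
        events_b = detect_bound(rot.apply(gs) + t, rot.apply(DIS) + t)
        assert [e.gs_index for e in events_a] == [e.gs_index for e in events_b]


class TestFractionBound:
    def test_all_frames_bound(self):
        gs = np.zeros((10, 1, 3))  # at the Cys sulfur, 1 A from midpoint
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (10, 1, 1)))
        res = fraction_bound(GsTrajectory([rep]))
        assert res.mean == 1.0

    def test_counting_fixture_34_of_100(self):
        gs = np.full((100, 1, 3), 50.0)
        gs[:34] = 0.0  # first 34 frames bound
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (100, 1, 1)))
        res = fraction_bound(GsTrajectory([rep]))
        assert res.mean == pytest.approx(0.34)

    def test_normalization_reference_is_100pct(self):
        gs = np.zeros((10, 1, 3))
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (10, 1, 1)))
        res = fraction_bound(GsTrajectory([rep]))
        assert res.normalized_pct(res) == pytest.approx(100.0)

    def test_welch_t_equals_hand_computation(self):
        a = FractionBoundResult(np.array([0.30, 0.32, 0.28, 0.31]), 5.5)
        b = FractionBoundResult(np.array([0.10, 0.12, 0.09, 0.11]), 5.5)
        t, p = welch_ttest(a, b)
        ma, mb = a.fractions.mean(), b.fractions.mean()
        va, vb = a.fractions.var(ddof=1), b.fractions.var(ddof=1)
        t_hand = (ma - mb) / np.sqrt(va / 4 + vb / 4)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert 0 < p < 1

    def test_fractions_within_unit_interval(self):
        rng = np.random.default_rng(0)
        gs = rng.uniform(-20, 20, size=(200, 3, 3))
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (200, 1, 1)))
        res = fraction_bound(GsTrajectory([rep]))
        assert 0.0 <= res.mean <= 1.0


class TestSSSGeometry:
    def test_collinear_sulfurs_give_180(self):
        # GS- on the disulfide axis, opposite the moiety sulfur
        rep = single_frame([[-3.0, 0.0, 0.0]])
        geo = sss_geometry(GsTrajectory([rep]), vertex="cys")
        assert geo.table["s_s_s_angle"].iloc[0] == pytest.approx(180.0)

    def test_right_angle_fixture(self):
        rep = single_frame([[0.0, 3.0, 0.0]])  # above the Cys sulfur
        geo = sss_geometry(GsTrajectory([rep]), vertex="cys")
        assert geo.table["s_s_s_angle"].iloc[0] == pytest.approx(90.0)

    def test_vertex_convention_flag(self):
        rep = single_frame([[0.0, 3.0, 0.0]])
        at_gs = sss_geometry(GsTrajectory([rep]), vertex="gs")
        # angle at GS- sulfur between Cys-S and moiety-S
        expected = np.degrees(np.arccos(
            np.dot([0, -3, 0], [2, -3, 0])
            / (3.0 * np.linalg.norm([2, -3, 0]))))
        assert at_gs.table["s_s_s_angle"].iloc[0] == pytest.approx(expected)

    def test_r2_matches_brute_force_pearson(self):
        rng = np.random.default_rng(1)
        gs = np.zeros((10, 1, 3))
        gs[:, 0, 0] = rng.uniform(-4, 4, 10)
        gs[:, 0, 1] = rng.uniform(0.5, 3.0, 10)
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (10, 1, 1)))
        geo = sss_geometry(GsTrajectory([rep]))
        d = geo.table["s_s_distance"]
        a = geo.table["s_s_s_angle"]
        r_brute = np.corrcoef(d, a)[0, 1]
        assert geo.r2 == pytest.approx(r_brute ** 2, rel=1e-10)
        assert geo.pvalue == pytest.approx(sps.pearsonr(d, a).pvalue, rel=1e-9)

    def test_histogram_counts_all_events(self):
        rng = np.random.default_rng(2)
        gs = rng.uniform(-3, 3, size=(50, 2, 3))
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (50, 1, 1)))
        geo = sss_geometry(GsTrajectory([rep]))
        assert geo.hist.sum() == len(geo.table)

    def test_fewer_than_three_events_flagged(self):
        rep = single_frame([[0.0, 3.0, 0.0]])
        geo = sss_geometry(GsTrajectory([rep]))
        assert not geo.correlation_defined
        assert np.isnan(geo.r2)


class TestOccupationDensity:
    def test_stationary_molecule_single_voxel(self):
        gs = np.zeros((25, 1, 3))
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (25, 1, 1)))
        grid = occupation_density(GsTrajectory([rep]), spacing=1.0)
        assert grid.counts.max() == 25
        assert (grid.counts > 0).sum() == 1

    def test_counts_conserved_and_equal_bound_pairs(self):
        rng = np.random.default_rng(3)
        gs = rng.uniform(-8, 8, size=(100, 4, 3))
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (100, 1, 1)))
        traj = GsTrajectory([rep])
        n_events = len(binding_events(traj))
        for spacing in (2.0, 1.0, 0.25):
            grid = occupation_density(traj, spacing=spacing)
            assert grid.counts.sum() == n_events

    def test_two_site_fixture_two_components(self):
        gs = np.zeros((40, 1, 3))
        gs[:20] = [1.0, 4.0, 0.0]    # site A, 4 A above the midpoint
        gs[20:] = [1.0, -4.0, 0.0]   # site B, 4 A below
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (40, 1, 1)))
        grid = occupation_density(GsTrajectory([rep]), spacing=1.0)
        assert grid.components(level=1.0) == 2

    def test_no_bound_states_warns_empty(self):
        gs = np.full((5, 1, 3), 100.0)
        rep = TrajectoryReplicate(gs_xyz=gs,
                                  disulfide_xyz=np.tile(DIS, (5, 1, 1)))
        with pytest.warns(UserWarning, match="no bound states"):
            grid = occupation_density(GsTrajectory([rep]), spacing=1.0)
        assert grid.n_samples == 0


class TestLinearizePath:
    def _traj_from_path(self, path):
        path = np.asarray(path, dtype=float)
        gs = path[:, None, :]
        rep = TrajectoryReplicate(
            gs_xyz=gs, disulfide_xyz=np.tile(DIS, (len(path), 1, 1)))
        return GsTrajectory([rep])

    def test_straight_line_preserved(self):
        t = np.linspace(0, 1, 30)[:, None]
        path = np.array([20.0, 0.0, 0.0]) * (1 - t) + np.array([1.0, 0.0, 0.0]) * t
        traj = self._traj_from_path(path)
        ev = binding_events(traj)[-1]
        out, truncated = linearize_path(traj, ev, window=10, smooth=5)
        start = ev.frame - 9
        assert not truncated
        assert np.allclose(out, path[start:ev.frame + 1], atol=1e-9)

    def test_window_one_single_point(self):
        path = np.tile([1.0, 0.0, 0.0], (5, 1))
        traj = self._traj_from_path(path)
        ev = binding_events(traj)[0]
        out, _ = linearize_path(traj, ev, window=1)
        assert out.shape == (1, 3)

    def test_zigzag_moving_average_hand_computed(self):
        zig = np.array([[0, 0, 0], [1, 2, 0], [2, 0, 0], [3, 2, 0],
                        [1, 0, 0]], dtype=float)
        traj = self._traj_from_path(zig)
        ev = binding_events(traj)[-1]
        out, _ = linearize_path(traj, ev, window=5, smooth=3)
        expected = np.array([
            zig[0], zig[0:3].mean(axis=0), zig[1:4].mean(axis=0),
            zig[2:5].mean(axis=0), zig[4],
        ])
        assert np.allclose(out, expected)

    def test_truncation_flag(self):
        path = np.tile([1.0, 0.0, 0.0], (5, 1))
        traj = self._traj_from_path(path)
        ev = binding_events(traj)[2]
        _, truncated = linearize_path(traj, ev, window=10)
        assert truncated


class TestClustering:
    def test_rmsd_matches_independent_superposition_oracle(self):
        """Kabsch RMSD vs scipy's align_vectors on <=5-atom instances."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(3, 6)
            a = rng.normal(size=(n, 3))
            rot = Rotation.random(rng=rng)
            b = rot.apply(a) + rng.normal(size=3)
            # exact superposition possible: RMSD must vanish
            assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)
            b_noisy = b + rng.normal(0, 0.3, size=(n, 3))
            _, oracle = Rotation.align_vectors(
                a - a.mean(0), b_noisy - b_noisy.mean(0))
            # align_vectors rssd -> rmsd
            assert kabsch_rmsd(a, b_noisy) == pytest.approx(
                oracle / np.sqrt(n), abs=1e-9)

    def test_rmsd_three_atom_hand_case(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        b = a @ Rotation.from_euler("z", 90, degrees=True).as_matrix().T + 5.0
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_poses_single_cluster(self):
        pose = np.random.default_rng(5).normal(size=(4, 3))
        poses = np.tile(pose, (6, 1, 1))
        cl = cluster_poses(poses, k=2)
        assert cl.populations.tolist() == [6]
        assert cl.rmsd_matrix.max() < 1e-9

    def test_two_separated_groups_found(self):
        rng = np.random.default_rng(6)
        base1 = rng.normal(size=(4, 3))
        base2 = base1 + np.linspace(0, 6, 4)[:, None] * np.array([0, 0, 1.0])
        poses = np.array(
            [base1 + rng.normal(0, 0.05, (4, 3)) for _ in range(6)]
            + [base2 + rng.normal(0, 0.05, (4, 3)) for _ in range(4)])
        cl = cluster_poses(poses, k=2)
        assert cl.populations.tolist() == [6, 4]
        assert set(cl.labels[:6]) == {0}
        assert set(cl.labels[6:]) == {1}
        # representatives live in their own clusters
        assert cl.labels[cl.representatives[0]] == 0
        assert cl.labels[cl.representatives[1]] == 1

    def test_singleton_input_one_cluster(self):
        cl = cluster_poses(np.zeros((1, 3, 3)), k=2)
        assert cl.populations.tolist() == [1]
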