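"""Group geometry and order parameters against hand-computed cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalkit import GroupTrajectory, make_line
from shoalkit import group_metrics as gm


class TestNND:
    def test_collinear_hand_case(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        assert np.allclose(gm.nearest_neighbour_distance(pos), [1.0, 1.0, 2.0])

    def test_coincident_pair(self):
        pos = np.zeros((2, 2))
        assert np.allclose(gm.nearest_neighbour_distance(pos), 0.0)

    def test_equilateral_triangle(self):
        s = 7.0
        pos = s * np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        assert np.allclose(gm.nearest_neighbour_distance(pos), s)

    def test_single_fish_rejected(self):
        with pytest.raises(ValueError):
            gm.nearest_neighbour_distance(np.zeros((1, 2)))


class TestIID:
    def test_pair_distance(self):
        pos = np.array([[0.0, 0.0], [5.0, 0.0]])
        assert gm.cohesion_iid(pos) == pytest.approx(5.0)

    def test_unit_square_brute_force(self):
        pos = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        expected = (4 * 1 + 2 * np.sqrt(2)) / 6  # enumerated pairs
        assert gm.cohesion_iid(pos) == pytest.approx(expected)

    def test_ordered_equals_unordered_mean(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(6, 2))
        dmat = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        ordered_mean = dmat[~np.eye(6, dtype=bool)].mean()
        assert gm.cohesion_iid(pos) == pytest.approx(ordered_mean)

    def test_smallest_nnd_below_iid(self):
        # the closest pair distance is a pairwise minimum, so it cannot
        # exceed the mean pairwise distance
        rng = np.random.default_rng(4)
        pos = rng.normal(size=(30, 5, 2))
        assert np.all(
            gm.nearest_neighbour_distance(pos).min(axis=1) <= gm.cohesion_iid(pos) + 1e-12
        )


class TestPolarization:
    def test_anchor_cases(self):
        assert gm.polarization(np.array([37.0, 37.0, 37.0])) == pytest.approx(1.0)
        assert gm.polarization(np.array([0.0, 180.0])) == pytest.approx(0.0, abs=1e-12)
        assert gm.polarization(np.array([0.0, 90.0])) == pytest.approx(np.sqrt(2) / 2)

    @settings(deadline=None)
    @given(
        st.lists(st.floats(-180, 180, allow_nan=False), min_size=1, max_size=12)
    )
    def test_bounds(self, headings):
        rho = gm.polarization(np.array(headings))
        assert -1e-12 <= rho <= 1 + 1e-12

    def test_all_nan_gives_nan(self):
        assert np.isnan(gm.polarization(np.array([np.nan, np.nan])))


class TestGroupFrame:
    def test_fish_ahead_and_behind(self):
        # two fish along the y axis, group travelling north
        pos = np.array([[0.0, 10.0], [0.0, -10.0]])
        out = gm.group_frame_transform(pos, psi_c=0.0)
        assert out["sigma"][0] == pytest.approx(0.0)
        assert out["yprime"][0] == pytest.approx(10.0)
        assert bool(out["front"][0]) and not bool(out["front"][1])
        assert abs(out["sigma"][1]) == pytest.approx(180.0)
        assert out["yprime"][1] == pytest.approx(-10.0)

    def test_left_flank_rotation(self):
        # group travelling east, fish due north of centroid -> left flank
        pos = np.array([[0.0, 50.0], [0.0, -50.0]])
        out = gm.group_frame_transform(pos, psi_c=90.0)
        assert out["sigma"][0] == pytest.approx(-90.0)
        assert out["xprime"][0] == pytest.approx(-50.0)
        assert out["yprime"][0] == pytest.approx(0.0, abs=1e-9)

    def test_isometry(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(20, 5, 2)) * 30
        psi = rng.uniform(-180, 180, size=20)
        out = gm.group_frame_transform(pos, psi)
        assert np.allclose(np.hypot(out["xprime"], out["yprime"]), out["cd"])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(size=(4, 5, 2)) * 20
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pos @ rot.T + np.array([12.0, -7.0])
        assert np.allclose(
            gm.nearest_neighbour_distance(moved), gm.nearest_neighbour_distance(pos)
        )
        assert np.allclose(gm.cohesion_iid(moved), gm.cohesion_iid(pos))
        # sigma is invariant once the centroid heading is rotated along
        psi = np.full(4, 20.0)
        psi_rot = psi - np.degrees(theta)  # clockwise-positive convention
        out = gm.group_frame_transform(pos, psi)
        out_rot = gm.group_frame_transform(moved, psi_rot)
        assert np.allclose(out["sigma"], out_rot["sigma"], atol=1e-9)
        assert np.allclose(out["xprime"], out_rot["xprime"], atol=1e-9)


class TestFrontFraction:
    def test_permanent_leader(self):
        leader = make_line(40, 0, 100, start=(0.0, 81.2), individual_id="L")
        trailer = make_line(40, 0, 100, start=(0.0, 0.0), individual_id="T")
        g = GroupTrajectory([leader, trailer])
        gs = gm.compute_group_series(g)
        ff = gm.front_fraction(gs.front, gs.centroid_valid)
        assert ff[0] == pytest.approx(1.0)
        assert ff[1] == pytest.approx(0.0)

    def test_fractions_bounded(self):
        rng = np.random.default_rng(7)
        front = rng.uniform(size=(50, 5)) > 0.5
        ff = gm.front_fraction(front)
        assert np.all((ff >= 0) & (ff <= 1))

    def test_no_valid_frames_raises(self):
        with pytest.raises(ValueError):
            gm.front_fraction(np.ones((5, 3), bool), np.zeros(5, bool))


class TestPairwiseAndSummary:
    def test_relative_direction_wrap(self):
        theta = gm.pairwise_relative_direction(np.array([170.0, -170.0]))
        assert theta[0, 1] == pytest.approx(-20.0)
        assert theta[1, 0] == pytest.approx(20.0)
        assert np.allclose(np.diag(theta), 0.0)

    def test_parallel_and_antiparallel(self):
        theta = gm.pairwise_relative_direction(np.array([45.0, 45.0, -135.0]))
        assert theta[0, 1] == pytest.approx(0.0)
        assert abs(theta[0, 2]) == pytest.approx(180.0)

    def test_centroid_is_member_mean(self):
        from shoalkit.simulator import free_schooling_config, run_experiment

        res = run_experiment(free_schooling_config(n_steps=100), seed=2)
        traj, _ = gm.centroid_series(res.group)
        assert np.allclose(traj.positions, res.group.positions().mean(axis=1))

    def test_mirrored_pair_centroid_static(self):
        a = make_line(10, 90, 20, start=(0.0, 5.0), individual_id="a")
        b_pos = -a.positions
        from shoalkit import Trajectory

        b = Trajectory("b", b_pos, fps=a.fps)
        g = GroupTrajectory([a, b])
        traj, kin = gm.centroid_series(g)
        assert np.allclose(traj.positions, 0.0)
        assert np.allclose(kin.speed[:-1], 0.0)

    def test_mean_median_speed_two_fish(self):
        a = make_line(10, 0, 50, individual_id="a")
        b = make_line(20, 0, 50, start=(5.0, 0.0), individual_id="b")
        summary = gm.group_summary(GroupTrajectory([a, b]))
        assert summary["group"]["mean_median_speed_mm_s"] == pytest.approx(15.0)

    def test_summary_deterministic(self):
        from shoalkit.simulator import free_schooling_config, run_experiment

        res1 = run_experiment(free_schooling_config(n_steps=100), seed=11)
        res2 = run_experiment(free_schooling_config(n_steps=100), seed=11)
        s1 = gm.group_summary(res1.group)
        s2 = gm.group_summary(res2.group)
        assert s1["group"] == s2["group"]
        assert s1["per_fish"].equals(s2["per_fish"])

    def test_center_distance_rank(self):
        ranks = gm.center_distance_rank(np.array([3.0, 1.0, 2.0]))
        assert np.allclose(ranks, [3, 1, 2])
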