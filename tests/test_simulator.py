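"""Model update rules and emergent behaviour of the agent-based simulator."""

import numpy as np
import pytest
from scipy.stats import binomtest, spearmanr

from shoalkit import group_metrics as gm
from shoalkit.simulator import (
    BatchSimulation,
    SimConfig,
    Simulation,
    apply_noise_and_turn,
    desired_directions,
    free_schooling_config,
    foraging_config,
    init_population,
    run_batch,
    run_experiment,
    social_vectors,
)

EAST = np.array([1.0, 0.0])
NORTH = np.array([0.0, 1.0])


class TestInitPopulation:
    def test_deterministic_under_seed(self):
        cfg = SimConfig()
        p1 = init_population(cfg, 5)
        p2 = init_population(cfg, 5)
        assert np.array_equal(p1.positions, p2.positions)
        assert np.array_equal(p1.speeds, p2.speeds)

    def test_homogeneous_limit(self):
        cfg = SimConfig(speed_sd=0.0, omega_sd=0.0)
        p = init_population(cfg, 1)
        assert np.allclose(p.speeds, cfg.speed_mean)
        assert np.allclose(p.omegas, cfg.omega_mean)

    def test_gamma_moments(self):
        # sample mean of k*theta = 0.02 within 3 standard errors
        cfg = SimConfig(speed_distribution="gamma", n_agents=100_000)
        p = init_population(cfg, 0)
        se = np.sqrt(cfg.gamma_shape * cfg.gamma_scale**2 / cfg.n_agents)
        assert abs(p.speeds.mean() - 0.02) < 3 * se

    def test_traits_positive(self):
        cfg = SimConfig(speed_mean=0.1, speed_sd=0.5, n_agents=500)
        p = init_population(cfg, 1)
        assert (p.speeds > 0).all()
        assert (p.omegas >= 0).all()

    def test_invalid_agent_count(self):
        with pytest.raises(ValueError):
            SimConfig(n_agents=0)


class TestSocialVector:
    def _cfg(self, **kw):
        return SimConfig(**kw)

    def test_repulsion_points_away(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.5]])  # neighbour ahead at 0.5 < r_r
        dirs = np.stack([NORTH, NORTH])
        s, _ = social_vectors(pos, dirs, self._cfg())
        assert np.allclose(s[0] / np.linalg.norm(s[0]), -NORTH)

    def test_pure_alignment(self):
        # neighbour at distance 3 in the orientation zone, moving east
        pos = np.array([[0.0, 0.0], [0.0, 3.0]])
        dirs = np.stack([NORTH, EAST])
        s, _ = social_vectors(pos, dirs, self._cfg())
        assert np.allclose(s[0] / np.linalg.norm(s[0]), EAST)

    def test_blind_angle_hides_neighbour_behind(self):
        # neighbour directly behind, within the 90-degree blind cone
        pos = np.array([[0.0, 0.0], [0.0, -3.0]])
        dirs = np.stack([NORTH, NORTH])
        s, _ = social_vectors(pos, dirs, self._cfg())
        assert np.allclose(s[0], 0.0)

    def test_repulsion_is_omnidirectional(self):
        # collision avoidance ignores the blind angle
        pos = np.array([[0.0, 0.0], [0.0, -0.5]])
        dirs = np.stack([NORTH, NORTH])
        s, _ = social_vectors(pos, dirs, self._cfg())
        assert np.allclose(s[0] / np.linalg.norm(s[0]), NORTH)

    def test_attraction_beyond_orientation_zone(self):
        pos = np.array([[0.0, 0.0], [0.0, 10.0]])
        dirs = np.stack([NORTH, EAST])
        s, _ = social_vectors(pos, dirs, self._cfg())
        assert np.allclose(s[0] / np.linalg.norm(s[0]), NORTH)

    def test_coincident_positions_logged(self):
        pos = np.zeros((2, 2))
        dirs = np.stack([NORTH, NORTH])
        s, n_co = social_vectors(pos, dirs, self._cfg(), np.random.default_rng(0))
        assert n_co == 2
        assert np.isfinite(s).all()


class TestDesiredDirection:
    def test_omega_zero_social_only(self):
        cfg = SimConfig()
        pop = init_population(cfg, 0)
        pop.omegas[:] = 0.0
        s = np.tile(EAST, (cfg.n_agents, 1)) * 2.0
        d = desired_directions(pop, s, cfg)
        assert np.allclose(d, EAST)

    def test_cue_overrides_inertia(self):
        cfg = SimConfig()
        pop = init_population(cfg, 0)
        pop.positions[:] = 0.0
        pop.omegas[:] = 1.0
        s = np.zeros((cfg.n_agents, 2))
        cue = np.array([[20.0, 0.0]])  # within r_c = 30
        d = desired_directions(pop, s, cfg, cue)
        assert np.allclose(d, EAST)

    def test_diagonal_vector_sum(self):
        cfg = SimConfig()
        pop = init_population(cfg, 0)
        pop.directions[:] = NORTH  # goal = inertia = north
        pop.omegas[:] = 1.0
        s = np.tile(EAST, (cfg.n_agents, 1))
        d = desired_directions(pop, s, cfg)
        assert np.allclose(d, np.sqrt(0.5) * (EAST + NORTH))

    def test_zero_resultant_keeps_heading(self):
        cfg = SimConfig()
        pop = init_population(cfg, 0)
        pop.omegas[:] = 0.0
        d = desired_directions(pop, np.zeros((cfg.n_agents, 2)), cfg)
        assert np.allclose(d, pop.directions)


class TestNoiseAndTurn:
    def test_within_turn_budget_reaches_target(self):
        cfg = SimConfig(noise_sd=0.0)  # cap = 60 * 0.1 = 6 degrees
        target = np.array([np.sin(np.deg2rad(3)), np.cos(np.deg2rad(3))])
        new = apply_noise_and_turn(NORTH, target, cfg)
        assert np.allclose(new, target)

    def test_capped_turn_is_exactly_six_degrees(self):
        cfg = SimConfig(noise_sd=0.0)
        new = apply_noise_and_turn(NORTH, EAST, cfg)
        turned = np.degrees(np.arccos(np.clip(np.dot(new, NORTH), -1, 1)))
        assert turned == pytest.approx(6.0)
        assert new[0] > 0  # turned toward the east target

    def test_identity_when_aligned(self):
        cfg = SimConfig(noise_sd=0.0)
        assert np.allclose(apply_noise_and_turn(NORTH, NORTH, cfg), NORTH)

    def test_noise_is_seeded(self):
        cfg = SimConfig()
        a = apply_noise_and_turn(NORTH, NORTH, cfg, np.random.default_rng(9))
        b = apply_noise_and_turn(NORTH, NORTH, cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestStepping:
    def test_single_agent_straight_line(self):
        cfg = SimConfig(
            n_agents=1, omega_sd=0.0, omega_mean=0.0, noise_sd=0.0, speed_sd=0.0
        )
        sim = Simulation(cfg, 3)
        d0 = sim.directions[0, 0].copy()
        sim.run(100)
        disp = sim.positions[0, 0] - sim.history[0][0, 0]
        assert np.allclose(disp / np.linalg.norm(disp), d0)
        assert np.linalg.norm(disp) == pytest.approx(
            cfg.speed_mean * cfg.dt * 100, rel=1e-9
        )

    def test_unit_directions_maintained(self):
        sim = Simulation(free_schooling_config(n_steps=200), 4)
        sim.run(200)
        norms = np.linalg.norm(sim.directions, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_periodic_wrap_preserves_direction(self):
        cfg = SimConfig(
            n_agents=1,
            boundary="periodic",
            omega_mean=0.0,
            omega_sd=0.0,
            noise_sd=0.0,
            speed_sd=0.0,
            arena_size=50.0,
        )
        sim = Simulation(cfg, 0)
        sim.positions[0, 0] = [49.95, 25.0]
        sim.directions[0, 0] = EAST
        sim.step()
        wrapped = sim.positions_wrapped[0, 0]
        assert wrapped[0] == pytest.approx(0.05, abs=1e-9)
        assert np.allclose(sim.directions[0, 0], EAST)

    def test_circular_boundary_contains_agents(self):
        cfg = foraging_config(n_steps=0, speed_mean=2.0)
        sim = Simulation(cfg, 1)
        sim.run(2000)
        radial = np.linalg.norm(np.asarray(sim.history)[:, 0], axis=-1)
        assert radial.max() <= cfg.arena_radius + 1e-9

    def test_group_stays_cohesive(self):
        """Default zonal parameters keep 5-agent groups connected (no
        permanent fission) in nearly all replicates."""
        ok = 0
        results = run_batch(free_schooling_config(), list(range(50)))
        for res in results:
            iid = gm.cohesion_iid(res.positions[-500:])
            ok += iid.max() < 60.0  # an order of magnitude above typical IID
        assert ok >= 48  # >= 95% of 50 runs

    def test_batch_matches_scalar(self):
        cfg = free_schooling_config(n_steps=100)
        scalar = run_experiment(cfg, 21)
        batch = run_batch(cfg, [20, 21])[1]
        assert np.array_equal(scalar.positions, batch.positions)


class TestFeeding:
    def test_binomial_expectation(self):
        # an agent parked on a patch for 10,000 steps at f = 0.001 eats ~10
        cfg = foraging_config(n_agents=1, items_per_patch=50, speed_mean=1e-6,
                              speed_sd=0.0, noise_sd=0.0, omega_mean=0.0,
                              omega_sd=0.0)
        sim = Simulation(cfg, 0)
        sim.positions[0, 0] = sim.patch_centers[0, 0]
        sim.speeds[0, 0] = 1e-9  # stay parked
        sim.run(10_000)
        eaten = int(sim.items_eaten.sum())
        assert 3 <= eaten <= 20  # within the binomial(10^4, 0.001) bulk
        assert len(sim.events[0]) == eaten

    def test_empty_patch_not_consumed(self):
        cfg = foraging_config(n_agents=2, items_per_patch=0)
        sim = Simulation(cfg, 0)
        sim.positions[0] = sim.patch_centers[0, 0]
        sim.run(200)
        assert sim.items_eaten.sum() == 0

    def test_food_conservation(self):
        cfg = foraging_config(items_per_patch=5, n_steps=0)
        sim = Simulation(cfg, 2)
        sim.positions[0] = sim.patch_centers[0, 0]  # all agents on a patch
        total = cfg.n_patches * cfg.items_per_patch
        for _ in range(3000):
            sim.step()
            assert sim.patch_items.sum() + sim.items_eaten.sum() == total

    def test_last_item_eaten_once(self):
        cfg = foraging_config(
            n_agents=5, n_patches=1, items_per_patch=1, feeding_rate=1.0
        )
        sim = Simulation(cfg, 3)
        sim.positions[0] = sim.patch_centers[0, 0]
        sim.step()
        assert sim.items_eaten.sum() == 1
        # ties break toward the lowest agent index
        assert sim.events[0][0][1] == 0


class TestEmergentAssortment:
    def test_run_protocol_shapes(self):
        res = run_experiment(free_schooling_config(), 0)
        assert res.group.n_frames == 2001
        assert len(res.snapshot_steps) == 11  # stored every 200 steps
        res_f = run_experiment(foraging_config(n_steps=1000), 1)
        assert len(res_f.snapshot_steps) == 3  # every 500 steps

    def test_replicates_differ_same_hash(self):
        cfg = free_schooling_config(n_steps=100)
        r1, r2 = run_batch(cfg, [1, 2])
        assert not np.array_equal(r1.positions, r2.positions)
        assert r1.config_hash == r2.config_hash

    def test_speed_predicts_front_position(self):
        """Faster members spend more time in front of the group centroid
        (sign-consistent across replicates)."""
        results = run_batch(free_schooling_config(), list(range(100, 140)))
        n_pos = 0
        for res in results:
            gs = gm.compute_group_series(res.group)
            ff = gm.front_fraction(gs.front, gs.centroid_valid)
            n_pos += spearmanr(res.speeds, ff).statistic > 0
        assert binomtest(n_pos, 40, alternative="greater").pvalue < 0.01

    def test_homogeneous_groups_exchangeable(self):
        """With zero trait spread, no agent index is systematically in
        front: the front fraction of agent 0 is at chance across replicates."""
        cfg = free_schooling_config(speed_sd=0.0, omega_sd=0.0, n_steps=1000)
        results = run_batch(cfg, list(range(200, 260)))
        agent0_high = 0
        for res in results:
            gs = gm.compute_group_series(res.group)
            ff = gm.front_fraction(gs.front, gs.centroid_valid)
            agent0_high += ff[0] > np.median(ff)
        p = binomtest(agent0_high, 60).pvalue
        assert p > 0.01  # no index effect
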