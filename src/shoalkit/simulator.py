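"""Zonal self-propelled-particle model with consistent individual differences.

Each agent carries a position, a unit direction, an intrinsic speed and a
goal-orientedness weight omega.  Speeds and omegas are drawn once per agent
per simulation (Gaussian, or Gamma for the right-skew robustness runs) and
held constant, representing consistent inter-individual differences; agents
can still effectively speed up or slow down through the tortuosity of their
paths.

Interactions follow the classic concentric-zone rules: repulsion inside
``r_r`` takes absolute priority; otherwise agents align with neighbours in
the orientation zone and are attracted to neighbours in the attraction zone,
both restricted to a field of perception (360 - blind angle) degrees.  The
social direction is reconciled with a goal vector (current motion, or the
nearest detected food cue) weighted by omega, perturbed by wrapped-Gaussian
heading noise, and applied subject to a maximum turning rate.

Arenas: unbounded (free schooling), periodic (wrap at ``arena_size``, with
minimum-image interactions; stored trajectories stay unwrapped so the
analysis modules see continuous paths), or circular (foraging; a narrow edge
zone redirects agents toward the centre, and depletable food patches sit in
the arena).

Replicate batches run vectorised (:func:`run_batch`); each replicate owns
its RNG stream, so a batch is bit-identical to the same seeds run one at a
time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fixtures import CircularArena, FoodPatch, GroupTrajectory, Trajectory

__all__ = [
    "SimConfig",
    "AgentState",
    "Population",
    "SimResult",
    "free_schooling_config",
    "foraging_config",
    "init_population",
    "social_vectors",
    "desired_directions",
    "apply_noise_and_turn",
    "Simulation",
    "run_experiment",
    "run_batch",
]

Boundary = Literal["unbounded", "periodic", "circular"]


@dataclass(frozen=True)
class SimConfig:
    """Model parameters.

    Lengths are in model units (the repulsion radius, ~1 body length, is the
    unit of scale), time in model time units; one step advances ``dt``.
    """

    arena_size: float = 500.0  # A; circular mode uses radius A/2
    r_r: float = 1.0  # zone of repulsion
    r_o: float = 6.0  # zone of orientation (outer radius)
    r_a: float = np.inf  # zone of attraction (outer radius)
    blind_angle: float = 90.0  # degrees behind the agent (perception 270)
    max_turn: float = 60.0  # degrees per time unit
    speed_mean: float = 1.0  # explored range 0.1-2.0
    speed_sd: float = 0.1
    omega_mean: float = 0.05  # explored range 0.01-0.1
    omega_sd: float = 0.01
    dt: float = 0.1
    noise_sd: float = float(np.degrees(0.05))  # wrapped-Gaussian heading error, deg
    cue_radius: float = 30.0  # r_c
    n_patches: int = 3
    items_per_patch: int = 50
    patch_radius: float = 10.0
    feeding_rate: float = 0.001  # per agent per step while on a patch
    n_agents: int = 5
    boundary: Boundary = "unbounded"
    speed_distribution: Literal["gaussian", "gamma"] = "gaussian"
    gamma_shape: float = 0.4
    gamma_scale: float = 0.05
    edge_zone_frac: float = 0.04  # width of the wall-avoidance zone, of radius
    release_radius: float = 5.0  # initial-position spread around the centre
    n_steps: int = 2000
    store_every: int = 200
    literal_signs: bool = False  # audit switch: printed-sign variant of the
    # orientation/attraction sums (makes agents mutually repulsive)

    def __post_init__(self) -> None:
        if not (0 < self.r_r < self.r_o <= self.r_a):
            raise ValueError("zones must satisfy 0 < r_r < r_o <= r_a")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if min(self.speed_sd, self.omega_sd, self.noise_sd, self.feeding_rate) < 0:
            raise ValueError("rates and spreads must be non-negative")

    @property
    def arena_radius(self) -> float:
        return self.arena_size / 2.0

    def config_hash(self) -> str:
        d = asdict(self)
        d["r_a"] = "inf" if np.isinf(d["r_a"]) else d["r_a"]
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def free_schooling_config(**overrides) -> SimConfig:
    """Free-schooling context: open arena, 2,000 steps, snapshots every 200."""
    base = dict(boundary="unbounded", n_steps=2000, store_every=200)
    base.update(overrides)
    return SimConfig(**base)


def foraging_config(**overrides) -> SimConfig:
    """Foraging context: circular arena with 3 food patches, 10,000 steps,
    snapshots every 500."""
    base = dict(boundary="circular", n_steps=10000, store_every=500)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class AgentState:
    """Single-agent view of the population state."""

    position: np.ndarray
    direction: np.ndarray
    intrinsic_speed: float
    omega: float
    items_eaten: int = 0


@dataclass
class Population:
    """Array-of-structs population state for one replicate."""

    positions: np.ndarray  # (n, 2)
    directions: np.ndarray  # (n, 2), unit
    speeds: np.ndarray  # (n,)
    omegas: np.ndarray  # (n,)
    items_eaten: np.ndarray  # (n,) int

    @property
    def n(self) -> int:
        return len(self.speeds)

    def as_agent_states(self) -> list[AgentState]:
        return [
            AgentState(
                self.positions[i].copy(),
                self.directions[i].copy(),
                float(self.speeds[i]),
                float(self.omegas[i]),
                int(self.items_eaten[i]),
            )
            for i in range(self.n)
        ]


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    """Normalise along the last axis, mapping zero vectors to zero."""
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, v / norm, 0.0)


def init_population(config: SimConfig, seed: int | np.random.Generator) -> Population:
    """Draw per-agent traits and initial states.

    Speeds: Normal(speed_mean, speed_sd) with non-positive draws resampled
    (floor 1e-6), or Gamma(shape, scale) when configured.  Omegas:
    Normal(omega_mean, omega_sd) floored at 0.  Positions are scattered in a
    disc of ``release_radius`` at the arena centre; directions are uniform.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_agents
    if config.speed_distribution == "gamma":
        speeds = rng.gamma(config.gamma_shape, config.gamma_scale, size=n)
        speeds = np.maximum(speeds, 1e-6)
    else:
        speeds = rng.normal(config.speed_mean, config.speed_sd, size=n)
        for _ in range(1000):
            bad = speeds <= 0
            if not bad.any():
                break
            speeds[bad] = rng.normal(config.speed_mean, config.speed_sd, size=bad.sum())
        speeds = np.maximum(speeds, 1e-6)
    omegas = np.maximum(rng.normal(config.omega_mean, config.omega_sd, size=n), 0.0)
    r = config.release_radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * np.pi, size=n)
    center = (
        np.full(2, config.arena_size / 2.0)
        if config.boundary == "periodic"
        else np.zeros(2)
    )
    positions = center + np.stack([r * np.sin(ang), r * np.cos(ang)], axis=1)
    dang = rng.uniform(0, 2 * np.pi, size=n)
    directions = np.stack([np.sin(dang), np.cos(dang)], axis=1)
    return Population(positions, directions, speeds, omegas, np.zeros(n, dtype=int))


# ---------------------------------------------------------------------------
# Batched update rules.  Shapes: positions/directions (R, n, 2) for R
# replicates; the public single-group wrappers below use R = 1.

def _social_batch(
    positions: np.ndarray,
    directions: np.ndarray,
    config: SimConfig,
    rngs: Sequence[np.random.Generator] | None,
) -> tuple[np.ndarray, int]:
    R, n = positions.shape[:2]
    diff = positions[:, None, :, :] - positions[:, :, None, :]  # [r,i,j]=c_j-c_i
    if config.boundary == "periodic":
        diff -= config.arena_size * np.round(diff / config.arena_size)
    dist = np.linalg.norm(diff, axis=-1)
    idx = np.arange(n)
    dist[:, idx, idx] = np.inf
    off_diag = ~np.eye(n, dtype=bool)
    coincident = (dist == 0) & off_diag
    n_coincident = int(coincident.sum())
    if n_coincident:
        for r in range(R):
            m = coincident[r]
            if not m.any():
                continue
            rng = rngs[r] if rngs is not None else np.random.default_rng()
            ang = rng.uniform(0, 2 * np.pi, size=int(m.sum()))
            diff[r][m] = np.stack([np.sin(ang), np.cos(ang)], axis=1)
            dist[r][m] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(np.isfinite(dist)[..., None], diff / dist[..., None], 0.0)

    # perception field: neighbour within (360 - blind)/2 degrees of the
    # direction of motion; the blind area is behind the agent
    cos_half = np.cos(np.deg2rad((360.0 - config.blind_angle) / 2.0))
    cosang = np.einsum("rijk,rik->rij", unit, directions)
    perceived = cosang >= cos_half

    rep_mask = dist < config.r_r
    any_rep = rep_mask.any(axis=2)
    s_rep = -(unit * rep_mask[..., None]).sum(axis=2)

    orient_mask = (dist >= config.r_r) & (dist <= config.r_o) & perceived
    attract_mask = (dist > config.r_o) & (dist <= config.r_a) & perceived
    o_sum = (directions[:, None, :, :] * orient_mask[..., None]).sum(axis=2)
    a_sum = (unit * attract_mask[..., None]).sum(axis=2)
    if config.literal_signs:
        o_sum, a_sum = -o_sum, -a_sum
    s_soc = _normalize_rows(o_sum) + _normalize_rows(a_sum)
    return np.where(any_rep[..., None], s_rep, s_soc), n_coincident


def _desired_batch(
    positions: np.ndarray,
    directions: np.ndarray,
    omegas: np.ndarray,
    s: np.ndarray,
    config: SimConfig,
    cue_centers: np.ndarray | None,
    cue_active: np.ndarray | None,
) -> np.ndarray:
    g = directions.copy()
    if cue_centers is not None and cue_centers.shape[1]:
        d2 = np.linalg.norm(
            positions[:, :, None, :] - cue_centers[:, None, :, :], axis=-1
        )
        if cue_active is not None:
            d2 = np.where(cue_active[:, None, :], d2, np.inf)
        nearest = d2.argmin(axis=2)  # (R, n)
        R, n = nearest.shape
        ri = np.arange(R)[:, None]
        dmin = d2[ri, np.arange(n)[None, :], nearest]
        within = dmin <= config.cue_radius
        to_cue = _normalize_rows(cue_centers[ri, nearest] - positions)
        g = np.where(within[..., None], to_cue, g)
    d = _normalize_rows(s) + omegas[..., None] * g
    dhat = _normalize_rows(d)
    zero = (dhat == 0).all(axis=-1)
    return np.where(zero[..., None], directions, dhat)


def _rotate(vectors: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Rotate vectors along the last axis by per-vector angles
    (counterclockwise positive)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y = vectors[..., 0], vectors[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def _turn_batch(
    current: np.ndarray,
    desired: np.ndarray,
    config: SimConfig,
    rngs: Sequence[np.random.Generator] | None,
) -> np.ndarray:
    cur = _normalize_rows(current)
    des = _normalize_rows(desired)
    if config.noise_sd > 0 and rngs is not None:
        R, n = des.shape[:2]
        eps = np.stack(
            [rng.normal(0.0, np.deg2rad(config.noise_sd), size=n) for rng in rngs]
        )
        des = _rotate(des, eps)
    cross = cur[..., 0] * des[..., 1] - cur[..., 1] * des[..., 0]
    dot = np.einsum("...i,...i->...", cur, des)
    ang = np.arctan2(cross, dot)
    cap = np.deg2rad(config.max_turn * config.dt)
    return _normalize_rows(_rotate(cur, np.clip(ang, -cap, cap)))


# -- public single-group forms (the update rules the model is defined by) ---

def social_vectors(
    positions: np.ndarray,
    directions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Social component of each agent's desired direction.

    Repulsion (omnidirectional, highest priority): when any neighbour sits
    inside ``r_r`` the result is the negative sum of unit vectors toward
    those neighbours and all other zones are ignored.  Otherwise the result
    is the sum of the normalised orientation term (neighbour headings within
    ``r_o``) and the normalised attraction term (unit vectors toward
    neighbours within ``r_a``), each restricted to the perception field.

    Returns ``(s, n_coincident)``; coincident neighbours are repelled along
    a random direction and counted.
    """
    s, n_co = _social_batch(
        np.asarray(positions, float)[None],
        np.asarray(directions, float)[None],
        config,
        [rng] if rng is not None else None,
    )
    return s[0], n_co


def desired_directions(
    pop: Population,
    s: np.ndarray,
    config: SimConfig,
    cue_positions: np.ndarray | None = None,
    cue_active: np.ndarray | None = None,
) -> np.ndarray:
    """Reconcile the social vector with the goal vector: d = s_hat + omega * g_hat.

    The goal vector points along current motion unless a cue (food patch
    with items remaining) lies within ``cue_radius``, in which case it
    points at the nearest such cue.  Zero resultants keep the previous
    direction.
    """
    cues = None if cue_positions is None else np.asarray(cue_positions, float)[None]
    active = None if cue_active is None else np.asarray(cue_active, bool)[None]
    return _desired_batch(
        pop.positions[None],
        pop.directions[None],
        pop.omegas[None],
        np.asarray(s, float)[None],
        config,
        cues,
        active,
    )[0]


def apply_noise_and_turn(
    current: np.ndarray,
    desired: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Perturb the desired direction by wrapped-Gaussian noise, then turn
    from the current direction toward it by at most ``max_turn * dt``.

    Ties at exactly 180 degrees resolve to the positive (counterclockwise)
    arc, deterministically.
    """
    single = np.asarray(current).ndim == 1
    cur = np.atleast_2d(np.asarray(current, float))[None]
    des = np.atleast_2d(np.asarray(desired, float))[None]
    out = _turn_batch(cur, des, config, [rng] if rng is not None else None)[0]
    return out[0] if single else out


class BatchSimulation:
    """Stepping engine for a batch of replicates sharing one config.

    Each replicate has its own RNG stream seeded with its own seed, and
    consumes draws in a fixed order (trait draws, patch placement, then per
    step: coincident repairs, heading noise, feeding), so results are
    independent of the batch composition.

    Trajectories are recorded every step (analysis grade).  In periodic
    mode the recorded positions are unwrapped (continuous);
    ``positions_wrapped`` folds them into [0, arena_size).
    """

    def __init__(self, config: SimConfig, seeds: Sequence[int]):
        self.config = config
        self.seeds = [int(s) for s in seeds]
        self.rngs = [np.random.default_rng(s) for s in self.seeds]
        R, n = len(self.seeds), config.n_agents
        pops = [init_population(config, rng) for rng in self.rngs]
        self.positions = np.stack([p.positions for p in pops])
        self.directions = np.stack([p.directions for p in pops])
        self.speeds = np.stack([p.speeds for p in pops])
        self.omegas = np.stack([p.omegas for p in pops])
        self.items_eaten = np.zeros((R, n), dtype=int)
        self.time = 0.0
        self.step_index = 0
        self.n_coincident = 0
        self.patch_centers: np.ndarray | None = None  # (R, P, 2)
        self.patch_items: np.ndarray | None = None  # (R, P)
        self.events: list[list[tuple[float, int, int]]] = [[] for _ in range(R)]
        self.depletion_time = np.full(R, np.nan)
        if config.boundary == "circular" and config.n_patches > 0:
            self._place_patches()
        self.history: list[np.ndarray] = [self.positions.copy()]

    @property
    def n_replicates(self) -> int:
        return len(self.seeds)

    def _place_patches(self) -> None:
        """Patches in a roughly equilateral polygon, in the radial band
        between 37.5% and 87.5% of the arena radius (the experimental
        layout - patches between 5 cm from the wall and 15 cm from the
        centre of a 40 cm-radius tank - rescaled)."""
        cfg = self.config
        R_arena = cfg.arena_radius
        centers = np.empty((self.n_replicates, cfg.n_patches, 2))
        for r, rng in enumerate(self.rngs):
            radius = rng.uniform(0.375 * R_arena, 0.875 * R_arena)
            base = rng.uniform(0, 2 * np.pi)
            ang = base + 2 * np.pi * np.arange(cfg.n_patches) / cfg.n_patches
            centers[r] = radius * np.stack([np.sin(ang), np.cos(ang)], axis=1)
        self.patch_centers = centers
        self.patch_items = np.full(
            (self.n_replicates, cfg.n_patches), cfg.items_per_patch
        )

    @property
    def positions_wrapped(self) -> np.ndarray:
        if self.config.boundary != "periodic":
            return self.positions
        return np.mod(self.positions, self.config.arena_size)

    def step(self) -> None:
        cfg = self.config
        s, n_co = _social_batch(
            self.positions_wrapped, self.directions, cfg, self.rngs
        )
        self.n_coincident += n_co
        cue_active = self.patch_items > 0 if self.patch_items is not None else None
        dhat = _desired_batch(
            self.positions,
            self.directions,
            self.omegas,
            s,
            cfg,
            self.patch_centers,
            cue_active,
        )
        if cfg.boundary == "circular":
            R_arena = cfg.arena_radius
            radial = np.linalg.norm(self.positions, axis=-1)
            in_edge = radial >= R_arena * (1.0 - cfg.edge_zone_frac)
            if in_edge.any():
                dhat = np.where(
                    in_edge[..., None], _normalize_rows(-self.positions), dhat
                )
        new_dirs = _turn_batch(self.directions, dhat, cfg, self.rngs)
        new_pos = self.positions + new_dirs * self.speeds[..., None] * cfg.dt
        if cfg.boundary == "circular":
            R_arena = cfg.arena_radius
            radial = np.linalg.norm(new_pos, axis=-1)
            outside = radial > R_arena
            if outside.any():
                scale = np.where(outside, R_arena / radial, 1.0)
                new_pos = new_pos * scale[..., None]
        if np.isnan(new_pos).any():
            raise RuntimeError(f"NaN position at step {self.step_index}")
        self.positions = new_pos
        self.directions = new_dirs
        self.step_index += 1
        self.time = self.step_index * cfg.dt
        if self.patch_items is not None:
            self._feeding_update()
        self.history.append(self.positions.copy())

    def _feeding_update(self) -> None:
        """Each agent on a patch consumes one item with probability
        ``feeding_rate`` per step while items remain; agents are processed
        in index order so the last item resolves deterministically."""
        cfg = self.config
        d = np.linalg.norm(
            self.positions[:, :, None, :] - self.patch_centers[:, None, :, :],
            axis=-1,
        )
        on_patch = d <= cfg.patch_radius
        candidates = np.flatnonzero(on_patch.any(axis=(1, 2)))
        for r in candidates:
            rng = self.rngs[r]
            for agent in np.flatnonzero(on_patch[r].any(axis=1)):
                hits = np.flatnonzero(on_patch[r, agent])
                patch = int(hits[d[r, agent, hits].argmin()])
                if self.patch_items[r, patch] <= 0:
                    continue
                if rng.uniform() < cfg.feeding_rate:
                    self.patch_items[r, patch] -= 1
                    self.items_eaten[r, agent] += 1
                    self.events[r].append((self.time, int(agent), patch))
            if np.isnan(self.depletion_time[r]) and self.patch_items[r].sum() == 0:
                self.depletion_time[r] = self.time

    def run(self, n_steps: int | None = None) -> None:
        for _ in range(n_steps if n_steps is not None else self.config.n_steps):
            self.step()

    def history_array(self) -> np.ndarray:
        """Recorded positions as one array, (n_steps+1, R, n, 2); the list
        of per-step snapshots is materialised once and replaced."""
        if len(self.history) != 1 or self.history[0].ndim != 4:
            arr = np.asarray(self.history)
            self.history = [arr]
        return self.history[0]

    def result(self, r: int = 0) -> "SimResult":
        """Package replicate ``r`` as a :class:`SimResult`."""
        cfg = self.config
        positions = self.history_array()[:, r]  # (steps+1, n, 2), a view
        patches = []
        if self.patch_centers is not None:
            for p in range(cfg.n_patches):
                events = [
                    (t, f"a{agent}")
                    for t, agent, patch in self.events[r]
                    if patch == p
                ]
                patches.append(
                    FoodPatch(
                        center=tuple(self.patch_centers[r, p]),
                        radius=cfg.patch_radius,
                        items_initial=cfg.items_per_patch,
                        item_events=events,
                    )
                )
        group = None
        if cfg.n_agents >= 2:
            trajectories = [
                Trajectory(
                    f"a{i}", positions[:, i], fps=1.0 / cfg.dt, body_length=1.0
                )
                for i in range(cfg.n_agents)
            ]
            arena = (
                CircularArena(cfg.arena_radius) if cfg.boundary == "circular" else None
            )
            group = GroupTrajectory(trajectories, arena=arena, patches=patches)
        snap_steps = np.arange(0, self.step_index + 1, cfg.store_every)
        dep = self.depletion_time[r]
        return SimResult(
            group=group,
            positions=positions,
            snapshots=positions[snap_steps],
            snapshot_steps=snap_steps,
            events=pd.DataFrame(
                self.events[r], columns=["time", "agent", "patch"]
            ),
            speeds=self.speeds[r].copy(),
            omegas=self.omegas[r].copy(),
            items_eaten=self.items_eaten[r].copy(),
            depletion_time=None if np.isnan(dep) else float(dep),
            config=cfg,
            seed=self.seeds[r],
        )

    @property
    def items_remaining(self) -> np.ndarray | int:
        if self.patch_items is None:
            return 0
        return self.patch_items.sum(axis=1)


class Simulation(BatchSimulation):
    """Single-replicate engine (a batch of one)."""

    def __init__(self, config: SimConfig, seed: int):
        super().__init__(config, [seed])

    @property
    def pop(self) -> Population:
        return Population(
            self.positions[0],
            self.directions[0],
            self.speeds[0],
            self.omegas[0],
            self.items_eaten[0],
        )


@dataclass
class SimResult:
    """Output of one simulated trial."""

    group: GroupTrajectory | None  # None for single-agent runs
    positions: np.ndarray  # (n_steps+1, n, 2) full resolution, unwrapped
    snapshots: np.ndarray  # thinned per the storage protocol
    snapshot_steps: np.ndarray
    events: pd.DataFrame  # time, agent, patch
    speeds: np.ndarray  # intrinsic per-agent speeds
    omegas: np.ndarray
    items_eaten: np.ndarray
    depletion_time: float | None  # time all patches emptied; None if censored
    config: SimConfig
    seed: int

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def mean_item_latency(self) -> float:
        """Mean per-item consumption latency, censoring uneaten items at the
        trial end - the depletion-speed statistic (smaller = faster
        depletion).  Defined for foraging runs."""
        provisioned = self.config.n_patches * self.config.items_per_patch
        horizon = self.config.n_steps * self.config.dt
        times = np.sort(self.events["time"].to_numpy(float))
        lat = np.concatenate([times, np.full(provisioned - len(times), horizon)])
        return float(lat.mean())


def run_experiment(config: SimConfig, seed: int) -> SimResult:
    """Run one trial: full-resolution trajectories (fps = 1/dt, body length
    1 model unit), thinned snapshots, and the feeding event log."""
    sim = BatchSimulation(config, [seed])
    sim.run()
    return sim.result(0)


def run_batch(config: SimConfig, seeds: Sequence[int]) -> list[SimResult]:
    """Run replicates vectorised; equivalent to mapping
    :func:`run_experiment` over ``seeds``, replicate by replicate."""
    sim = BatchSimulation(config, seeds)
    sim.run()
    return [sim.result(r) for r in range(sim.n_replicates)]
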