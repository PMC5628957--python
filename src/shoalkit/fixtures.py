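"""Trajectory containers, parametric test trajectories, and tabular I/O.

Positions are 2-D (x to the right, y "north"/up) in millimetres, sampled at a
uniform frame rate.  Headings throughout the package are measured clockwise
from the +y axis in degrees, in (-180, 180].

The parametric generators (:func:`make_line`, :func:`make_circle`,
:func:`make_delayed_follower`) produce trajectories whose kinematics are known
in closed form; they are the oracle surface for the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "GroupTrajectory",
    "FoodPatch",
    "CircularArena",
    "CoverDisc",
    "TrajectoryFormatError",
    "make_line",
    "make_circle",
    "make_varying_speed_line",
    "make_speed_profile_line",
    "make_delayed_follower",
    "read_trajectories",
    "write_trajectories",
]

#: Mean body length of the study fish, mm.
DEFAULT_BODY_LENGTH = 40.6
#: Video frame rate of the group recordings, frames/s.
DEFAULT_FPS = 24.0


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory table violates the tabular schema."""


@dataclass(frozen=True)
class CircularArena:
    """Circular arena centred on the origin with the given radius (mm)."""

    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arena radius must be positive")


@dataclass(frozen=True)
class CoverDisc:
    """Disc-shaped plant-cover region (centre in mm, radius in mm)."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cover radius must be positive")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of positions (..., 2) inside the disc."""
        d = np.linalg.norm(np.asarray(positions, float) - np.asarray(self.center), axis=-1)
        return d <= self.radius


@dataclass
class FoodPatch:
    """A food patch: a square grid (experiments) or a disc (simulations).

    Exactly one of ``half_width`` (square half-side, mm) or ``radius``
    (disc radius, mm) must be given.  ``item_events`` records consumptions
    as ``(time_s, consumer_id)`` with non-decreasing times.
    """

    center: tuple[float, float]
    half_width: float | None = None
    radius: float | None = None
    items_initial: int = 5
    item_events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.half_width is None) == (self.radius is None):
            raise ValueError("specify exactly one of half_width or radius")
        size = self.half_width if self.half_width is not None else self.radius
        if size is None or size <= 0:
            raise ValueError("patch size must be positive")
        if self.items_initial < 0:
            raise ValueError("items_initial must be non-negative")
        if len(self.item_events) > self.items_initial:
            raise ValueError("items consumed exceed items provisioned")
        times = [t for t, _ in self.item_events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("item event times must be non-decreasing")

    @property
    def items_remaining(self) -> int:
        return self.items_initial - len(self.item_events)

    def boundary_distance(self, positions: np.ndarray) -> np.ndarray:
        """Distance (mm) from positions (..., 2) to the patch boundary.

        Zero for points on or over the patch.
        """
        p = np.asarray(positions, float) - np.asarray(self.center)
        if self.radius is not None:
            return np.maximum(np.linalg.norm(p, axis=-1) - self.radius, 0.0)
        # square patch: distance to the axis-aligned square
        ex = np.maximum(np.abs(p[..., 0]) - self.half_width, 0.0)
        ey = np.maximum(np.abs(p[..., 1]) - self.half_width, 0.0)
        return np.hypot(ex, ey)


@dataclass
class Trajectory:
    """Positions of one individual at a uniform time step of ``1/fps`` s."""

    individual_id: str
    positions: np.ndarray
    fps: float = DEFAULT_FPS
    body_length: float = DEFAULT_BODY_LENGTH

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_frames, 2) array")
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame index / fps)."""
        return np.arange(self.n_frames) / self.fps

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]


@dataclass
class GroupTrajectory:
    """Aligned trajectories of the members of one group plus arena geometry."""

    trajectories: list[Trajectory]
    arena: CircularArena | None = None
    cover: CoverDisc | None = None
    patches: list[FoodPatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trajectories) < 2:
            raise ValueError("a group needs at least 2 members")
        ids = [t.individual_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        t0 = self.trajectories[0]
        for t in self.trajectories[1:]:
            if t.n_frames != t0.n_frames:
                raise ValueError("member trajectories must share frame indices")
            if t.fps != t0.fps:
                raise ValueError("member trajectories must share fps")

    @property
    def ids(self) -> list[str]:
        return [t.individual_id for t in self.trajectories]

    @property
    def n(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return self.trajectories[0].n_frames

    @property
    def fps(self) -> float:
        return self.trajectories[0].fps

    @property
    def body_length(self) -> float:
        return self.trajectories[0].body_length

    def positions(self) -> np.ndarray:
        """Stacked positions, shape ``(n_frames, n, 2)``."""
        return np.stack([t.positions for t in self.trajectories], axis=1)

    def member(self, individual_id: str) -> Trajectory:
        for t in self.trajectories:
            if t.individual_id == individual_id:
                return t
        raise KeyError(individual_id)


# ---------------------------------------------------------------------------
# Parametric fixtures

def heading_to_unit(heading_deg: float | np.ndarray) -> np.ndarray:
    """Unit vector(s) for headings in degrees clockwise from +y."""
    h = np.deg2rad(np.asarray(heading_deg, float))
    return np.stack([np.sin(h), np.cos(h)], axis=-1)


def make_line(
    speed: float,
    heading: float,
    n_frames: int,
    fps: float = DEFAULT_FPS,
    *,
    start: tuple[float, float] = (0.0, 0.0),
    individual_id: str = "line",
    body_length: float = DEFAULT_BODY_LENGTH,
) -> Trajectory:
    """Constant-velocity path.

    Parameters
    ----------
    speed : mm/s, must be >= 0.
    heading : degrees clockwise from +y ("north").
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    t = np.arange(n_frames)[:, None] / fps
    pos = np.asarray(start, float) + speed * t * heading_to_unit(heading)
    return Trajectory(individual_id, pos, fps=fps, body_length=body_length)


def make_circle(
    radius: float,
    angular_rate: float,
    n_frames: int,
    fps: float = DEFAULT_FPS,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
    individual_id: str = "circle",
    body_length: float = DEFAULT_BODY_LENGTH,
) -> Trajectory:
    """Uniform circular motion.

    ``angular_rate`` is in rad/s, positive clockwise (matching the heading
    sign convention).  Closed forms: speed = r|omega|, |acceleration| =
    r*omega**2, turning speed = omega (in degrees/s after conversion).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    t = np.arange(n_frames) / fps
    theta = phase + angular_rate * t
    pos = np.asarray(center, float) + radius * np.stack(
        [np.sin(theta), np.cos(theta)], axis=1
    )
    return Trajectory(individual_id, pos, fps=fps, body_length=body_length)


def make_speed_profile_line(
    speeds: np.ndarray,
    fps: float = DEFAULT_FPS,
    *,
    heading: float = 0.0,
    start: tuple[float, float] = (0.0, 0.0),
    individual_id: str = "profile",
    body_length: float = DEFAULT_BODY_LENGTH,
) -> Trajectory:
    """Straight path whose per-frame speed follows ``speeds`` (mm/s).

    The displacement over frame k uses the speed at frame k, so a forward
    finite difference recovers the profile exactly (up to the final frame).
    """
    v = np.asarray(speeds, float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("speeds must be a 1-D array with >= 2 entries")
    if (v < 0).any():
        raise ValueError("speeds must be non-negative")
    dist = np.concatenate([[0.0], np.cumsum(v[:-1]) / fps])
    pos = np.asarray(start, float) + dist[:, None] * heading_to_unit(heading)
    return Trajectory(individual_id, pos, fps=fps, body_length=body_length)


def make_varying_speed_line(
    base_speed: float,
    amplitude: float,
    period_s: float,
    n_frames: int,
    fps: float = DEFAULT_FPS,
    *,
    heading: float = 0.0,
    start: tuple[float, float] = (0.0, 0.0),
    individual_id: str = "varying",
    body_length: float = DEFAULT_BODY_LENGTH,
) -> Trajectory:
    """Straight path with sinusoidally modulated speed.

    Speed at frame t is ``base_speed + amplitude * sin(2*pi*t/(fps*period_s))``
    (mm/s); the heading is constant.  The modulation gives the speed series
    the structure needed to plant and recover lead-follow delays.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if amplitude >= base_speed:
        raise ValueError("amplitude must be below base_speed (speed stays positive)")
    t = np.arange(n_frames)
    v = base_speed + amplitude * np.sin(2 * np.pi * t / (fps * period_s))
    return make_speed_profile_line(
        v,
        fps,
        heading=heading,
        start=start,
        individual_id=individual_id,
        body_length=body_length,
    )


def make_delayed_follower(
    leader: Trajectory,
    delay_frames: int,
    offset: tuple[float, float] = (0.0, 0.0),
    *,
    individual_id: str = "follower",
) -> Trajectory:
    """A copy of ``leader`` delayed by ``delay_frames`` and shifted by ``offset``.

    The first ``delay_frames`` frames are filled by extrapolating the
    leader's initial velocity backwards, so the follower trajectory has the
    same frame count as the leader and the planted delay is exact ground
    truth for the leadership analysis.
    """
    if delay_frames < 0:
        raise ValueError("delay_frames must be non-negative")
    if delay_frames >= leader.n_frames:
        raise ValueError("delay_frames must be smaller than the leader frame count")
    off = np.asarray(offset, float)
    pos = np.empty_like(leader.positions)
    if delay_frames == 0:
        pos[:] = leader.positions + off
    else:
        pos[delay_frames:] = leader.positions[:-delay_frames] + off
        v0 = leader.positions[1] - leader.positions[0]
        back = np.arange(-delay_frames, 0)[:, None]
        pos[:delay_frames] = leader.positions[0] + back * v0 + off
    return Trajectory(individual_id, pos, fps=leader.fps, body_length=leader.body_length)


# ---------------------------------------------------------------------------
# Tabular I/O
#
# Schema: CSV with header frame,id,x_mm,y_mm, one row per fish per frame,
# frames contiguous per id.  An optional sidecar (YAML or JSON) carries fps,
# body_length_mm, arena, cover and patch geometry.

def _sidecar_path(path: Path) -> Path:
    for ext in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(ext)
        if cand.exists() and cand != path:
            return cand
    return path.with_suffix(".yaml")


def _meta_to_dict(group: GroupTrajectory) -> dict:
    meta: dict = {
        "fps": float(group.fps),
        "body_length_mm": float(group.body_length),
    }
    if group.arena is not None:
        meta["arena"] = {"circular": {"radius_mm": float(group.arena.radius)}}
    if group.cover is not None:
        meta["cover"] = {
            "center_mm": [float(v) for v in group.cover.center],
            "radius_mm": float(group.cover.radius),
        }
    if group.patches:
        meta["patches"] = []
        for p in group.patches:
            d: dict = {
                "center_mm": [float(v) for v in p.center],
                "items_initial": int(p.items_initial),
            }
            if p.half_width is not None:
                d["half_width_mm"] = float(p.half_width)
            else:
                d["radius_mm"] = float(p.radius)
            if p.item_events:
                d["item_events"] = [[float(t), str(c)] for t, c in p.item_events]
            meta["patches"].append(d)
    return meta


def _meta_from_dict(meta: dict) -> dict:
    out: dict = {
        "fps": float(meta.get("fps", DEFAULT_FPS)),
        "body_length": float(meta.get("body_length_mm", DEFAULT_BODY_LENGTH)),
        "arena": None,
        "cover": None,
        "patches": [],
    }
    if "arena" in meta and meta["arena"]:
        circ = meta["arena"].get("circular")
        if circ:
            out["arena"] = CircularArena(float(circ["radius_mm"]))
    if "cover" in meta and meta["cover"]:
        c = meta["cover"]
        out["cover"] = CoverDisc(tuple(c["center_mm"]), float(c["radius_mm"]))
    for p in meta.get("patches", []) or []:
        out["patches"].append(
            FoodPatch(
                center=tuple(p["center_mm"]),
                half_width=p.get("half_width_mm"),
                radius=p.get("radius_mm"),
                items_initial=int(p.get("items_initial", 5)),
                item_events=[(float(t), str(c)) for t, c in p.get("item_events", [])],
            )
        )
    return out


def write_trajectories(group: GroupTrajectory, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a group to the CSV schema plus a YAML sidecar with metadata."""
    path = Path(path)
    frames = np.arange(group.n_frames)
    parts = [
        pd.DataFrame(
            {
                "frame": frames,
                "id": t.individual_id,
                "x_mm": t.positions[:, 0],
                "y_mm": t.positions[:, 1],
            }
        )
        for t in group.trajectories
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
    if sidecar:
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(_meta_to_dict(group), fh, sort_keys=False)


def read_trajectories(path: str | Path, *, sidecar: str | Path | None = None) -> GroupTrajectory:
    """Read a group from the CSV schema; rejects gaps and duplicate rows."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["frame", "id", "x_mm", "y_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    for col in ("x_mm", "y_mm"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2  # 1-based plus header
            raise TrajectoryFormatError(f"{path}: non-numeric {col} at file row {row}")
    dup = df.duplicated(subset=["frame", "id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise TrajectoryFormatError(f"{path}: duplicate (frame,id) at file row {row}")

    meta: dict = {}
    sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = (json.load(fh) if sc.suffix == ".json" else yaml.safe_load(fh)) or {}
    parsed = _meta_from_dict(meta)

    ids = list(dict.fromkeys(df["id"].astype(str)))
    all_frames = np.sort(df["frame"].unique())
    expected = np.arange(all_frames[0], all_frames[-1] + 1)
    trajectories = []
    for ind in ids:
        sub = df[df["id"].astype(str) == ind].sort_values("frame")
        frames = sub["frame"].to_numpy()
        if len(frames) != len(expected) or not np.array_equal(frames, expected):
            gaps = np.setdiff1d(expected, frames)
            raise TrajectoryFormatError(
                f"{path}: id {ind} missing frame(s) {gaps[:5].tolist()}"
            )
        trajectories.append(
            Trajectory(
                ind,
                sub[["x_mm", "y_mm"]].to_numpy(float),
                fps=parsed["fps"],
                body_length=parsed["body_length"],
            )
        )
    return GroupTrajectory(
        trajectories,
        arena=parsed["arena"],
        cover=parsed["cover"],
        patches=parsed["patches"],
    )
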