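"""Per-individual kinematics from discrete tracking positions.

Velocity is a forward finite difference, acceleration a central difference,
turning speed a wrapped forward difference of the heading.  Headings are
degrees clockwise from +y in (-180, 180]; with velocity v = (u, w) the
heading is atan2(u, w), so due north is 0 deg and due east is +90 deg.
Turning is positive clockwise.

Frames where a quantity is undefined (the trailing frame of a forward
difference, heading at zero speed) are NaN; ``valid`` masks mark them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .fixtures import Trajectory

__all__ = [
    "KinematicsSeries",
    "smooth",
    "velocity",
    "speed",
    "heading",
    "acceleration",
    "turning_speed",
    "wrap_angle",
    "compute",
]


def wrap_angle(angle_deg: np.ndarray | float) -> np.ndarray:
    """Wrap angles (degrees) to (-180, 180], preserving the shorter arc."""
    a = np.asarray(angle_deg, float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped


@dataclass
class KinematicsSeries:
    """Frame-aligned kinematics for one individual.

    All arrays have the trajectory's frame count; undefined frames are NaN.
    """

    velocity: np.ndarray  # (T, 2) mm/s
    speed: np.ndarray  # (T,) mm/s
    heading: np.ndarray  # (T,) degrees in (-180, 180]
    acceleration: np.ndarray  # (T, 2) mm/s^2
    turning_speed: np.ndarray  # (T,) degrees/s
    fps: float
    body_length: float

    @property
    def valid(self) -> np.ndarray:
        """Mask of frames with defined velocity."""
        return ~np.isnan(self.speed)

    @property
    def speed_bls(self) -> np.ndarray:
        """Speed in body lengths per second."""
        return self.speed / self.body_length


def smooth(trajectory: Trajectory, window: int = 15, polyorder: int = 3) -> Trajectory:
    """Savitzky-Golay smoothing of x and y independently.

    Exact on polynomial paths of degree <= ``polyorder``; the frame count is
    unchanged.  The 15-frame window matches the tracking pipeline the
    analysis was designed for.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > trajectory.n_frames:
        raise ValueError("window exceeds the trajectory frame count")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    sm = savgol_filter(trajectory.positions, window, polyorder, axis=0)
    return Trajectory(
        trajectory.individual_id, sm, fps=trajectory.fps, body_length=trajectory.body_length
    )


def velocity(trajectory: Trajectory) -> np.ndarray:
    """Forward-difference velocity, (T, 2) mm/s; the final frame is NaN."""
    pos = trajectory.positions
    v = np.full_like(pos, np.nan)
    v[:-1] = (pos[1:] - pos[:-1]) * trajectory.fps
    return v


def speed(velocity_series: np.ndarray) -> np.ndarray:
    """Speed as the norm of the velocity vector."""
    return np.linalg.norm(velocity_series, axis=-1)


def heading(velocity_series: np.ndarray) -> np.ndarray:
    """Heading in degrees clockwise from +y; NaN where speed is zero."""
    v = np.asarray(velocity_series, float)
    psi = np.degrees(np.arctan2(v[..., 0], v[..., 1]))
    s = np.linalg.norm(v, axis=-1)
    psi = np.where(s > 0, psi, np.nan)
    # atan2 yields [-180, 180]; fold -180 to +180 for the (-180, 180] range
    return np.where(psi == -180.0, 180.0, psi)


def acceleration(trajectory: Trajectory) -> np.ndarray:
    """Central-difference acceleration, (T, 2) mm/s^2; edge frames are NaN."""
    if trajectory.n_frames < 3:
        raise ValueError("acceleration needs at least 3 frames")
    pos = trajectory.positions
    a = np.full_like(pos, np.nan)
    a[1:-1] = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) * trajectory.fps**2
    return a


def turning_speed(heading_series: np.ndarray, fps: float) -> np.ndarray:
    """Wrapped forward difference of the heading, degrees/s.

    Differences beyond +-180 deg are folded onto the shorter arc, so a step
    from 179 deg to -179 deg is +2 deg, not -358 deg.  NaN where either
    heading is undefined or at the trailing frame.
    """
    psi = np.asarray(heading_series, float)
    gamma = np.full_like(psi, np.nan)
    gamma[:-1] = wrap_angle(psi[1:] - psi[:-1]) * fps
    return gamma


def compute(trajectory: Trajectory, smooth_window: int | None = None, polyorder: int = 3) -> KinematicsSeries:
    """Full kinematics pipeline: optional smoothing, then differencing.

    Smoothing (when requested) is applied to the positions once and all
    derivatives are taken from the smoothed path.
    """
    traj = trajectory
    if smooth_window is not None:
        traj = smooth(traj, smooth_window, polyorder)
    v = velocity(traj)
    s = speed(v)
    psi = heading(v)
    acc = acceleration(traj) if traj.n_frames >= 3 else np.full_like(v, np.nan)
    gamma = turning_speed(psi, traj.fps)
    return KinematicsSeries(
        velocity=v,
        speed=s,
        heading=psi,
        acceleration=acc,
        turning_speed=gamma,
        fps=traj.fps,
        body_length=traj.body_length,
    )
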