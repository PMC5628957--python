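"""Group-referenced geometry and order parameters.

Given aligned member trajectories this module computes, per frame: nearest
neighbour distance (NND), group-centroid kinematics, centre distance (CD),
the group-frame transform (bearing from centroid delta, relative bearing
sigma, rotated coordinates (x', y') with +y' the direction of group travel),
front occupancy, pairwise relative headings, mean inter-individual distance
(IID, the cohesion measure) and polarization rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import kinematics
from .fixtures import GroupTrajectory, Trajectory
from .kinematics import KinematicsSeries, wrap_angle

__all__ = [
    "GroupFrameSeries",
    "nearest_neighbour_distance",
    "centroid_series",
    "group_frame_transform",
    "front_fraction",
    "pairwise_relative_direction",
    "cohesion_iid",
    "polarization",
    "center_distance_rank",
    "compute_group_series",
    "group_summary",
]

#: Centroid speeds below this (mm/s) leave the travel direction undefined.
MIN_CENTROID_SPEED = 1e-6


def _frame_distance_matrix(positions: np.ndarray) -> np.ndarray:
    """Pairwise distance matrices for positions of shape (T, n, 2) or (n, 2)."""
    pos = np.asarray(positions, float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    T, n = pos.shape[:2]
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    return dmat[0] if single else dmat


def nearest_neighbour_distance(positions: np.ndarray) -> np.ndarray:
    """Per-fish NND for one frame (n, 2) or a stack (T, n, 2)."""
    pos = np.asarray(positions, float)
    if pos.shape[-2] < 2:
        raise ValueError("NND needs at least 2 fish")
    dmat = _frame_distance_matrix(pos)
    eye = np.eye(pos.shape[-2], dtype=bool)
    dmat = np.where(eye, np.inf, dmat)
    return dmat.min(axis=-1)


def cohesion_iid(positions: np.ndarray) -> np.ndarray | float:
    """Mean inter-individual (pairwise) distance, the cohesion measure.

    The mean over ordered pairs equals the mean over unordered pairs, so the
    unordered mean is used.
    """
    pos = np.asarray(positions, float)
    if pos.shape[-2] < 2:
        raise ValueError("IID needs at least 2 fish")
    dmat = _frame_distance_matrix(pos)
    n = pos.shape[-2]
    iu = np.triu_indices(n, k=1)
    return dmat[..., iu[0], iu[1]].mean(axis=-1)


def polarization(headings_deg: np.ndarray) -> np.ndarray | float:
    """Alignment order parameter rho in [0, 1].

    rho = |mean of the heading unit vectors|; 0 is complete non-alignment,
    1 complete alignment.  NaN headings are excluded; all-NaN frames give NaN.
    """
    psi = np.deg2rad(np.asarray(headings_deg, float))
    sin_sum = np.nansum(np.sin(psi), axis=-1)
    cos_sum = np.nansum(np.cos(psi), axis=-1)
    n_valid = np.sum(~np.isnan(psi), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.hypot(sin_sum, cos_sum) / n_valid
    return np.where(n_valid > 0, rho, np.nan)


def centroid_series(group: GroupTrajectory, smooth_window: int | None = None) -> tuple[Trajectory, KinematicsSeries]:
    """Centroid trajectory (mean member position per frame) and its kinematics."""
    pos = group.positions().mean(axis=1)
    traj = Trajectory("centroid", pos, fps=group.fps, body_length=group.body_length)
    return traj, kinematics.compute(traj, smooth_window=smooth_window)


def group_frame_transform(positions: np.ndarray, psi_c: np.ndarray | float) -> dict[str, np.ndarray]:
    """Transform member positions into the travelling group frame.

    Parameters
    ----------
    positions : (T, n, 2) or (n, 2) member positions, mm.
    psi_c : centroid heading(s), degrees clockwise from +y; NaN masks a frame.

    Returns arrays ``delta`` (bearing of each fish from the centroid),
    ``sigma`` (that bearing relative to the direction of travel, wrapped to
    (-180, 180]), ``cd`` (centre distance), ``xprime``/``yprime`` (rotated
    coordinates; +y' forward, +x' right of travel) and the boolean ``front``
    flag (y' > 0).  The transform is an isometry: hypot(x', y') = CD.
    """
    pos = np.asarray(positions, float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    psi = np.atleast_1d(np.asarray(psi_c, float))[:, None]
    centroid = pos.mean(axis=1, keepdims=True)
    rel = pos - centroid
    cd = np.linalg.norm(rel, axis=-1)
    delta = np.degrees(np.arctan2(rel[..., 0], rel[..., 1]))
    sigma = wrap_angle(delta - psi)
    sig_r = np.deg2rad(sigma)
    xprime = cd * np.sin(sig_r)
    yprime = cd * np.cos(sig_r)
    front = yprime > 0
    out = {
        "delta": delta,
        "sigma": sigma,
        "cd": cd,
        "xprime": xprime,
        "yprime": yprime,
        "front": front,
    }
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def front_fraction(front: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Per-fish proportion of valid frames spent in front of the centroid.

    ``front`` is (T, n) boolean; ``valid`` a (T,) frame mask (frames with a
    defined centroid heading).  Raises if no frame is valid.
    """
    front = np.asarray(front, bool)
    if valid is None:
        valid = np.ones(front.shape[0], dtype=bool)
    valid = np.asarray(valid, bool)
    if valid.sum() == 0:
        raise ValueError("no valid frames for front fraction")
    return front[valid].mean(axis=0)


def pairwise_relative_direction(headings_deg: np.ndarray) -> np.ndarray:
    """Matrix of wrapped heading differences theta_ij = wrap(psi_i - psi_j).

    Antisymmetric up to the wrap; NaN where either heading is undefined.
    """
    psi = np.asarray(headings_deg, float)
    return wrap_angle(psi[..., :, None] - psi[..., None, :])


def center_distance_rank(cd: np.ndarray) -> np.ndarray:
    """Within-frame rank of centre distance: 1 = most central, n = most
    peripheral, mean ranks on ties.  ``cd`` is (T, n) or (n,)."""
    from scipy.stats import rankdata

    return rankdata(np.asarray(cd, float), axis=-1, method="average")


@dataclass
class GroupFrameSeries:
    """Frame-level group metrics for one trial."""

    nnd: np.ndarray  # (T, n) mm
    cd: np.ndarray  # (T, n) mm
    sigma: np.ndarray  # (T, n) degrees
    xprime: np.ndarray  # (T, n) mm
    yprime: np.ndarray  # (T, n) mm
    front: np.ndarray  # (T, n) bool
    iid: np.ndarray  # (T,) mm
    rho: np.ndarray  # (T,)
    centroid: Trajectory
    centroid_kin: KinematicsSeries
    member_kin: list[KinematicsSeries]
    ids: list[str]

    @property
    def centroid_valid(self) -> np.ndarray:
        """Frames where the centroid heading (direction of travel) is defined."""
        return (~np.isnan(self.centroid_kin.heading)) & (
            self.centroid_kin.speed > MIN_CENTROID_SPEED
        )


def compute_group_series(group: GroupTrajectory, smooth_window: int | None = None) -> GroupFrameSeries:
    """All frame-level metrics for a group trial in one pass."""
    member_kin = [
        kinematics.compute(t, smooth_window=smooth_window) for t in group.trajectories
    ]
    if smooth_window is not None:
        pos = np.stack(
            [kinematics.smooth(t, smooth_window).positions for t in group.trajectories],
            axis=1,
        )
    else:
        pos = group.positions()
    centroid_traj = Trajectory(
        "centroid", pos.mean(axis=1), fps=group.fps, body_length=group.body_length
    )
    centroid_kin = kinematics.compute(centroid_traj)
    psi_c = np.where(
        centroid_kin.speed > MIN_CENTROID_SPEED, centroid_kin.heading, np.nan
    )
    gf = group_frame_transform(pos, psi_c)
    headings = np.stack([k.heading for k in member_kin], axis=1)
    return GroupFrameSeries(
        nnd=nearest_neighbour_distance(pos),
        cd=gf["cd"],
        sigma=gf["sigma"],
        xprime=gf["xprime"],
        yprime=gf["yprime"],
        front=gf["front"],
        iid=cohesion_iid(pos),
        rho=polarization(headings),
        centroid=centroid_traj,
        centroid_kin=centroid_kin,
        member_kin=member_kin,
        ids=group.ids,
    )


def group_summary(group: GroupTrajectory, smooth_window: int | None = None) -> dict:
    """Per-trial summaries.

    Per fish: median speed, NND and CD (medians because the frame-level
    distributions are right-skewed).  Per group: mean IID and polarization,
    and the group speed both as the median centroid speed ("centroid" sense)
    and as the mean of the member median speeds (the group-speed convention
    used when comparing compositions) - reported separately.
    """
    gs = compute_group_series(group, smooth_window=smooth_window)
    per_fish = pd.DataFrame(
        {
            "id": gs.ids,
            "median_speed_mm_s": np.nanmedian(
                np.stack([k.speed for k in gs.member_kin], axis=1), axis=0
            ),
            "median_nnd_mm": np.median(gs.nnd, axis=0),
            "median_cd_mm": np.median(gs.cd, axis=0),
            "front_fraction": front_fraction(gs.front, gs.centroid_valid),
        }
    )
    group_level = {
        "mean_iid_mm": float(np.mean(gs.iid)),
        "mean_rho": float(np.nanmean(gs.rho)),
        "median_centroid_speed_mm_s": float(np.nanmedian(gs.centroid_kin.speed)),
        "mean_median_speed_mm_s": float(per_fish["median_speed_mm_s"].mean()),
    }
    return {"per_fish": per_fish, "group": group_level}
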