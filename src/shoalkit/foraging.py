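"""Foraging and hiding analytics, plus individual behavioural scores.

Patch discovery uses the vicinity rule: a fish is "at" a patch when it is
over the patch or within 30 mm of the patch boundary; the discoverer is the
first arrival during a trial.  Cover metrics describe refuge use around a
disc of plant cover: time out of cover, time out alone, and the order in
which fish leave cover on group excursions.  Behaviour scores condense the
two individual assays: an exploration ("boldness") score from time spent
out of cover, and a social-proximity score from distance to a confined
shoal (square-root transformed, inverted, then min-max scaled so higher
means a stronger proximity tendency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import CoverDisc, FoodPatch, GroupTrajectory

__all__ = [
    "ForagingEvents",
    "BehaviorScores",
    "patch_discovery",
    "cover_metrics",
    "depletion_latencies",
    "behavior_scores",
    "items_per_trial",
    "max_daily_intake",
]

#: Vicinity margin around a patch boundary, mm.
VICINITY_MM = 30.0
#: Bloodworms per patch in the experimental trials.
EXPERIMENT_ITEMS_PER_PATCH = 5
#: Food patches per trial.
EXPERIMENT_N_PATCHES = 3
#: Foraging trials per experimental day.
EXPERIMENT_TRIALS_PER_DAY = 2


def items_per_trial(
    n_patches: int = EXPERIMENT_N_PATCHES,
    items_per_patch: int = EXPERIMENT_ITEMS_PER_PATCH,
) -> int:
    """Food items provisioned per foraging trial (3 patches x 5 worms = 15)."""
    return n_patches * items_per_patch

def max_daily_intake(
    trials_per_day: int = EXPERIMENT_TRIALS_PER_DAY,
    n_patches: int = EXPERIMENT_N_PATCHES,
    items_per_patch: int = EXPERIMENT_ITEMS_PER_PATCH,
) -> int:
    """Theoretical per-fish daily maximum: every item of every trial (30)."""
    return trials_per_day * items_per_trial(n_patches, items_per_patch)


@dataclass
class ForagingEvents:
    """Discovery and feeding records for one trial."""

    discoveries: pd.DataFrame  # patch, id, time_s, order
    feedings: pd.DataFrame  # time_s, id, item_index
    provisioned: int

    def __post_init__(self) -> None:
        if len(self.feedings) > self.provisioned:
            raise ValueError("more feeding events than provisioned items")


def patch_discovery(
    group: GroupTrajectory,
    patches: list[FoodPatch] | None = None,
    *,
    vicinity_mm: float = VICINITY_MM,
) -> pd.DataFrame:
    """Arrival order of fish at each patch.

    Returns one row per (patch, fish) first arrival within the vicinity
    (over the patch or within ``vicinity_mm`` of its boundary), with columns
    ``patch``, ``id``, ``time_s``, ``order`` (1 = discoverer).  Simultaneous
    arrivals within one frame are ordered by fish id.  Fish that never enter
    the vicinity of a patch contribute no row; an undiscovered patch has no
    rows at all.
    """
    patches = patches if patches is not None else group.patches
    if not patches:
        raise ValueError("no patches defined")
    pos = group.positions()  # (T, n, 2)
    rows = []
    for p_idx, patch in enumerate(patches):
        dist = patch.boundary_distance(pos)  # (T, n)
        near = dist <= vicinity_mm
        for f_idx, fish in enumerate(group.ids):
            hits = np.flatnonzero(near[:, f_idx])
            if hits.size:
                rows.append(
                    {
                        "patch": p_idx,
                        "id": fish,
                        "frame": int(hits[0]),
                        "time_s": hits[0] / group.fps,
                    }
                )
    df = pd.DataFrame(rows, columns=["patch", "id", "frame", "time_s"])
    if len(df):
        df = df.sort_values(["patch", "frame", "id"], kind="stable").reset_index(drop=True)
        df["order"] = df.groupby("patch").cumcount() + 1
    else:
        df["order"] = pd.Series(dtype=int)
    return df


def _excursion_orders(out_mask: np.ndarray, centroid_out: np.ndarray, ids: list[str]) -> pd.DataFrame:
    """Leaving order per excursion.

    An excursion brackets a contiguous run of frames with the group centroid
    outside the cover disc; within each excursion, fish are ranked by the
    frame they first appear out of cover (fish that stay in get no rank).
    """
    T, n = out_mask.shape
    edges = np.flatnonzero(np.diff(centroid_out.astype(int)) == 1) + 1
    starts = list(edges)
    if centroid_out[0]:
        starts.insert(0, 0)
    rows = []
    for e_idx, start in enumerate(starts):
        end = start
        while end < T and centroid_out[end]:
            end += 1
        firsts = []
        for f in range(n):
            hits = np.flatnonzero(out_mask[start:end, f])
            if hits.size:
                firsts.append((int(hits[0]), ids[f]))
        firsts.sort()
        for order, (_, fish) in enumerate(firsts, start=1):
            rows.append({"excursion": e_idx, "id": fish, "order": order})
    return pd.DataFrame(rows, columns=["excursion", "id", "order"])


def cover_metrics(
    group: GroupTrajectory,
    cover: CoverDisc | None = None,
    *,
    food_available_until_s: float | None = None,
) -> dict:
    """Refuge-use statistics around a disc of cover.

    Per fish: proportion of frames out of cover, proportion out of cover
    alone (no other member concurrently out), and the mean order number for
    leaving cover across excursions.  Group level: mean number of fish out
    and the proportion of frames with every fish out.  When
    ``food_available_until_s`` is given, all proportions are restricted to
    frames before that time (the food-available window).
    """
    cover = cover if cover is not None else group.cover
    if cover is None:
        raise ValueError("no cover region defined")
    pos = group.positions()
    out = ~cover.contains(pos)  # (T, n): tracked point outside the disc
    window = np.ones(out.shape[0], bool)
    if food_available_until_s is not None:
        window = np.arange(out.shape[0]) / group.fps <= food_available_until_s
    out_w = out[window]
    n_out = out_w.sum(axis=1)
    alone = out_w & (n_out[:, None] == 1)
    centroid_out = ~cover.contains(pos.mean(axis=1))
    orders = _excursion_orders(out, centroid_out, group.ids)
    mean_order = (
        orders.groupby("id")["order"].mean()
        if len(orders)
        else pd.Series(dtype=float)
    )
    per_fish = pd.DataFrame(
        {
            "id": group.ids,
            "prop_out": out_w.mean(axis=0),
            "prop_out_alone": alone.mean(axis=0),
            "mean_leave_order": [mean_order.get(i, np.nan) for i in group.ids],
        }
    )
    return {
        "per_fish": per_fish,
        "group": {
            "mean_n_out": float(n_out.mean()),
            "all_out_proportion": float((n_out == out_w.shape[1]).mean()),
        },
        "excursions": orders,
    }


def depletion_latencies(
    feeding_times_s: np.ndarray | list[float],
    provisioned: int,
    trial_length_s: float,
) -> pd.DataFrame:
    """Per-item consumption latencies from trial start.

    Items never eaten are censored at the trial length.  Returns one row per
    provisioned item: ``item_index`` (1-based, in consumption order),
    ``latency_s``, ``censored``.
    """
    times = np.sort(np.asarray(feeding_times_s, float))
    if len(times) > provisioned:
        raise ValueError("more feeding events than provisioned items")
    n_censored = provisioned - len(times)
    lat = np.concatenate([times, np.full(n_censored, trial_length_s)])
    return pd.DataFrame(
        {
            "item_index": np.arange(1, provisioned + 1),
            "latency_s": lat,
            "censored": np.concatenate(
                [np.zeros(len(times), bool), np.ones(n_censored, bool)]
            ),
        }
    )


@dataclass
class BehaviorScores:
    """Cohort behaviour scores, one entry per fish."""

    ids: list[str]
    exploration: np.ndarray  # [0, 1]
    social_proximity: np.ndarray  # [0, 1]; higher = stronger proximity tendency
    relative_exploration: np.ndarray = field(default=None)  # type: ignore[assignment]
    relative_social_proximity: np.ndarray = field(default=None)  # type: ignore[assignment]
    single_trial_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        d = {
            "id": self.ids,
            "exploration": self.exploration,
            "social_proximity": self.social_proximity,
        }
        if self.relative_exploration is not None:
            d["relative_exploration"] = self.relative_exploration
            d["relative_social_proximity"] = self.relative_social_proximity
        return pd.DataFrame(d)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def behavior_scores(
    ids: list[str],
    prop_out_of_cover: np.ndarray,
    shoal_distance_mm: np.ndarray,
    groups: list[list[str]] | None = None,
) -> BehaviorScores:
    """Exploration and social-proximity scores from the two assays.

    Parameters
    ----------
    prop_out_of_cover : (n_fish, n_trials) proportions from the boldness
        assay; averaged across trials, then min-max scaled to [0, 1].
    shoal_distance_mm : (n_fish, n_trials) mean distances to the shoal
        compartment; averaged, square-root transformed, inverted
        (max - value) and min-max scaled, so higher = stronger proximity
        tendency.  The transform chain is strictly monotone decreasing in
        the raw distance.
    groups : optional partition of ids; when given, relative scores are
        focal score minus the mean score of the focal's group-mates.
    """
    prop = np.atleast_2d(np.asarray(prop_out_of_cover, float))
    dist = np.atleast_2d(np.asarray(shoal_distance_mm, float))
    if prop.shape[0] == 1 and len(ids) > 1:
        prop, dist = prop.T, dist.T
    warn = prop.shape[1] < 2 or dist.shape[1] < 2
    exploration = _minmax(prop.mean(axis=1))
    sq = np.sqrt(dist.mean(axis=1))
    social = _minmax(sq.max() - sq)
    rel_e = rel_s = None
    if groups is not None:
        idx = {i: k for k, i in enumerate(ids)}
        rel_e = np.full(len(ids), np.nan)
        rel_s = np.full(len(ids), np.nan)
        for members in groups:
            for focal in members:
                mates = [idx[m] for m in members if m != focal]
                if not mates:
                    continue
                f = idx[focal]
                rel_e[f] = exploration[f] - exploration[mates].mean()
                rel_s[f] = social[f] - social[mates].mean()
    return BehaviorScores(
        ids=list(ids),
        exploration=exploration,
        social_proximity=social,
        relative_exploration=rel_e,
        relative_social_proximity=rel_s,
        single_trial_warning=bool(warn),
    )
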