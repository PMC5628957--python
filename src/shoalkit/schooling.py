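"""Frame-wise schooling classification and the threshold robustness scan.

A frame counts as schooling when the group is cohesive (mean inter-individual
distance IID <= 160 mm), moves (centroid speed >= 0.5 BL/s), is aligned
(polarization rho >= 0.6) and has neither an outlier nor a group split.
Schooling is contrasted with swarming: cohesive but slow and/or unaligned.

The robustness scan re-classifies every trial under a 5x5x5 grid of
alternative thresholds (polarization 0.4-0.8 step 0.1, speed 1.0-3.0 cm/s
step 0.5, cohesion 100-220 mm step 30) and correlates the resulting
schooling proportions with a group covariate; the primary combination maps
onto the (0.6, 2.0 cm/s, 160 mm) grid point, leaving 124 alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .group_metrics import GroupFrameSeries, _frame_distance_matrix

__all__ = [
    "SplitConfig",
    "SchoolingCriteria",
    "detect_outlier_split",
    "classify_frames",
    "schooling_proportion",
    "robustness_grid",
    "grid_combinations",
    "trial_classifier_inputs",
]

OK, OUTLIER, SPLIT = 0, 1, 2

#: The robustness-scan threshold grid.
GRID_RHO = (0.4, 0.5, 0.6, 0.7, 0.8)
GRID_SPEED_CM_S = (1.0, 1.5, 2.0, 2.5, 3.0)
GRID_IID_MM = (100.0, 130.0, 160.0, 190.0, 220.0)
#: Grid point the primary criteria map to (0.5 BL/s = 2.03 cm/s at BL 40.6 mm).
PRIMARY_GRID_POINT = (0.6, 2.0, 160.0)


@dataclass(frozen=True)
class SplitConfig:
    """Outlier / group-split detection parameters.

    Fish whose pairwise distance is at most ``outlier_nnd_max`` body lengths
    are linked; a single isolated fish is an outlier, two or more separated
    sub-groups of >= 2 are a split.  4 BL is the same proximity cut-off used
    to gate the leadership analysis.
    """

    outlier_nnd_max: float = 4.0  # body lengths
    method: str = "connectivity"

    def __post_init__(self) -> None:
        if self.outlier_nnd_max <= 0:
            raise ValueError("outlier_nnd_max must be positive")


@dataclass(frozen=True)
class SchoolingCriteria:
    """Thresholds of the frame-wise schooling classifier (boundary inclusive)."""

    iid_max: float = 160.0  # mm
    vc_min: float = 0.5  # BL/s
    rho_min: float = 0.6
    split_rules: SplitConfig = field(default_factory=SplitConfig)

    def __post_init__(self) -> None:
        if self.iid_max <= 0 or self.vc_min <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.rho_min <= 1:
            raise ValueError("rho_min must be in (0, 1]")


def detect_outlier_split(
    positions: np.ndarray, body_length: float, config: SplitConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Classify frames as ok / outlier / split from member positions.

    Parameters
    ----------
    positions : (T, n, 2) or (n, 2) positions, mm.
    body_length : mm, scales the connectivity threshold.

    Returns ``(status, isolated)``: per-frame status code (OK=0, OUTLIER=1,
    SPLIT=2) and a per-fish boolean flag marking members outside the main
    component.
    """
    config = config or SplitConfig()
    pos = np.asarray(positions, float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    T, n = pos.shape[:2]
    if n < 2:
        raise ValueError("split detection needs at least 2 fish")
    thresh = config.outlier_nnd_max * body_length
    dmat = _frame_distance_matrix(pos)
    status = np.zeros(T, dtype=int)
    flags = np.zeros((T, n), dtype=bool)
    for t in range(T):
        adj = dmat[t] <= thresh
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp == 1:
            continue
        sizes = np.bincount(labels)
        if sizes.max() == n - 1 and (sizes == 1).sum() == 1:
            status[t] = OUTLIER
        elif (sizes >= 2).sum() >= 2:
            status[t] = SPLIT
        else:
            # several singletons off a main cluster: count as outlier frame
            status[t] = OUTLIER
        main = np.argmax(sizes)
        flags[t] = labels != main
    if single:
        return status[0], flags[0]
    return status, flags


def classify_frames(
    iid_mm: np.ndarray,
    vc_bls: np.ndarray,
    rho: np.ndarray,
    status: np.ndarray,
    criteria: SchoolingCriteria | None = None,
) -> np.ndarray:
    """Frame-wise schooling flags; NaN inputs yield NaN (frame excluded).

    True iff IID <= iid_max, centroid speed >= vc_min (BL/s), rho >= rho_min
    and the frame has no outlier or split.  Returns a float array with
    values 1.0 / 0.0 / NaN so excluded frames stay distinguishable.
    """
    criteria = criteria or SchoolingCriteria()
    iid = np.asarray(iid_mm, float)
    vc = np.asarray(vc_bls, float)
    rho = np.asarray(rho, float)
    status = np.asarray(status)
    defined = ~(np.isnan(iid) | np.isnan(vc) | np.isnan(rho))
    passing = (
        (iid <= criteria.iid_max)
        & (vc >= criteria.vc_min)
        & (rho >= criteria.rho_min)
        & (status == OK)
    )
    return np.where(defined, passing.astype(float), np.nan)


def schooling_proportion(flags: np.ndarray) -> float:
    """Schooling frames / classified frames; raises when none classified."""
    flags = np.asarray(flags, float)
    n = np.sum(~np.isnan(flags))
    if n == 0:
        raise ValueError("no classified frames")
    return float(np.nansum(flags) / n)


def trial_classifier_inputs(
    group_positions: np.ndarray,
    gs: GroupFrameSeries,
    body_length: float,
    split_rules: SplitConfig | None = None,
) -> dict[str, np.ndarray]:
    """Classifier inputs for one trial.

    ``group_positions`` is the (T, n, 2) position stack the metrics were
    computed from (needed for split detection).
    """
    status, _ = detect_outlier_split(group_positions, body_length, split_rules)
    return {
        "iid_mm": gs.iid,
        "vc_bls": gs.centroid_kin.speed / body_length,
        "rho": gs.rho,
        "status": status,
    }


def grid_combinations() -> list[tuple[float, float, float]]:
    """All (rho_min, speed cm/s, iid_max mm) grid combinations (125 incl.
    the primary)."""
    return list(product(GRID_RHO, GRID_SPEED_CM_S, GRID_IID_MM))


def robustness_grid(
    trials: list[dict[str, np.ndarray]],
    group_covariate: np.ndarray,
    body_length: float = 40.6,
) -> pd.DataFrame:
    """Schooling-proportion vs covariate correlation under every grid cell.

    Parameters
    ----------
    trials : one dict per trial with keys ``iid_mm``, ``vc_bls``, ``rho``,
        ``status`` (as from :func:`trial_classifier_inputs`).
    group_covariate : scalar per trial (e.g. group mean intrinsic speed).

    Returns a DataFrame with one row per grid combination: the thresholds,
    the Spearman correlation between per-trial schooling proportion and the
    covariate, its p value, and ``is_primary`` marking the cell the primary
    criteria map to.  ``df.attrs["n_alternatives"]`` counts the non-primary
    cells.
    """
    cov = np.asarray(group_covariate, float)
    if len(trials) != len(cov):
        raise ValueError("one covariate value per trial required")
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    rows = []
    for rho_min, speed_cm_s, iid_max in grid_combinations():
        vc_min_bls = speed_cm_s * 10.0 / body_length
        crit = SchoolingCriteria(iid_max=iid_max, vc_min=vc_min_bls, rho_min=rho_min)
        props = np.array(
            [
                schooling_proportion(
                    classify_frames(t["iid_mm"], t["vc_bls"], t["rho"], t["status"], crit)
                )
                for t in trials
            ]
        )
        if np.std(props) == 0 or np.std(cov) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = spearmanr(props, cov)
        rows.append(
            {
                "rho_min": rho_min,
                "speed_cm_s": speed_cm_s,
                "iid_max_mm": iid_max,
                "spearman_rho": r,
                "p_value": p,
                "is_primary": (rho_min, speed_cm_s, iid_max) == PRIMARY_GRID_POINT,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_alternatives"] = int((~df["is_primary"]).sum())
    return df
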