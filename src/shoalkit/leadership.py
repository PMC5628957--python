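"""Propagation-of-motion analysis: delayed dyadic correlations and
leadership networks.

For each dyad the speed (or heading) series of the two fish are correlated
at every lag from -3 s to +3 s in single-frame steps; the lag of the peak
correlation is the dyadic delay tau*.  A positive tau* for pair (i, j)
means i's changes precede j's, i.e. i leads.  Edges of the leadership
network point from leader to follower and are weighted by the delay in
seconds, following the delay-matrix construction used for pigeon flock
hierarchies.

Frames enter a dyad's correlation only when the two fish are less than
4 body lengths apart and both move faster than 1 body length per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .fixtures import GroupTrajectory
from .kinematics import KinematicsSeries

__all__ = [
    "DyadDelayResult",
    "eligible_frames",
    "delayed_correlation",
    "windowed_delay",
    "build_network",
    "analyse_group",
]

#: Lag scan half-width: 72 frames = 3 s at 24 fps.
DEFAULT_MAX_LAG = 72
#: Proximity gate, body lengths ("less than"): strict.
PROXIMITY_BL = 4.0
#: Speed gate, body lengths per second ("faster than"): strict.
MIN_SPEED_BLS = 1.0
#: Frames of eligible overlap below which a dyad is undefined (10 s at 24 fps).
DEFAULT_MIN_OVERLAP = 240


@dataclass
class DyadDelayResult:
    """Delay estimate for one ordered pair read as (leader-candidate i, j)."""

    pair: tuple[str, str]
    channel: str  # "speed" | "direction"
    delay_s: float | None  # positive: i precedes j; None when undefined
    peak_corr: float | None
    n_valid_frames: int
    lags: np.ndarray | None = None  # frames
    correlogram: np.ndarray | None = None

    @property
    def defined(self) -> bool:
        return self.delay_s is not None


def eligible_frames(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    speed_i: np.ndarray,
    speed_j: np.ndarray,
    body_length: float,
    *,
    proximity_bl: float = PROXIMITY_BL,
    min_speed_bls: float = MIN_SPEED_BLS,
) -> np.ndarray:
    """Frame mask: pair distance < proximity and both speeds above the floor."""
    dist = np.linalg.norm(np.asarray(pos_i, float) - np.asarray(pos_j, float), axis=-1)
    with np.errstate(invalid="ignore"):
        mask = (
            (dist < proximity_bl * body_length)
            & (speed_i > min_speed_bls * body_length)
            & (speed_j > min_speed_bls * body_length)
        )
    return mask & ~np.isnan(speed_i) & ~np.isnan(speed_j)


def _lag_correlation(
    series_i: np.ndarray,
    series_j: np.ndarray,
    mask: np.ndarray,
    lag: int,
    channel: str,
) -> tuple[float, int]:
    """Correlation between i at t and j at t+lag over jointly eligible frames."""
    T = len(series_i)
    if lag >= 0:
        ti = np.arange(0, T - lag)
    else:
        ti = np.arange(-lag, T)
    tj = ti + lag
    ok = mask[ti] & mask[tj]
    a, b = series_i[ti][ok], series_j[tj][ok]
    ok2 = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok2], b[ok2]
    n = len(a)
    if n < 3:
        return np.nan, n
    if channel == "speed":
        if a.std() == 0 or b.std() == 0:
            return np.nan, n
        return float(np.corrcoef(a, b)[0, 1]), n
    if channel == "direction":
        # mean cosine of the heading difference: the heading-unit-vector dot
        # product, safe under the +-180 deg wrap
        return float(np.mean(np.cos(np.deg2rad(a - b)))), n
    raise ValueError(f"unknown channel {channel!r}")


def delayed_correlation(
    series_i: np.ndarray,
    series_j: np.ndarray,
    fps: float,
    *,
    mask: np.ndarray | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    channel: str = "speed",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    pair: tuple[str, str] = ("i", "j"),
    keep_correlogram: bool = False,
) -> DyadDelayResult:
    """Scan lags in [-max_lag, +max_lag] frames and locate the peak.

    ``series_i``/``series_j`` are per-frame speed (mm/s) or heading
    (degrees) series; ``mask`` restricts to eligible frames.  tau* > 0 means
    i precedes j.  Ties at the peak resolve to the lag closest to zero
    (then to the positive lag).
    """
    series_i = np.asarray(series_i, float)
    series_j = np.asarray(series_j, float)
    if mask is None:
        mask = ~(np.isnan(series_i) | np.isnan(series_j))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        corr[k], counts[k] = _lag_correlation(series_i, series_j, mask, lag, channel)
    n_valid = int(mask.sum())
    usable = ~np.isnan(corr) & (counts >= min_overlap)
    if not usable.any():
        return DyadDelayResult(pair, channel, None, None, n_valid)
    cmax = np.nanmax(corr[usable])
    cand = lags[usable & (corr == cmax)]
    best = cand[np.lexsort((-np.sign(cand), np.abs(cand)))][0]
    return DyadDelayResult(
        pair,
        channel,
        float(best / fps),
        float(cmax),
        n_valid,
        lags=lags if keep_correlogram else None,
        correlogram=corr if keep_correlogram else None,
    )


def windowed_delay(
    series_i: np.ndarray,
    series_j: np.ndarray,
    fps: float,
    *,
    mask: np.ndarray | None = None,
    window_s: float = 30.0,
    overlap: float = 0.5,
    max_lag: int = DEFAULT_MAX_LAG,
    channel: str = "speed",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    pair: tuple[str, str] = ("i", "j"),
) -> DyadDelayResult:
    """Mean of per-window peak lags over sliding windows.

    The reported delay is the mean time point of the per-window maxima;
    windows without enough eligible overlap are skipped.
    """
    series_i = np.asarray(series_i, float)
    T = len(series_i)
    win = int(round(window_s * fps))
    step = max(1, int(round(win * (1 - overlap))))
    delays, peaks, n_total = [], [], 0
    for start in range(0, max(1, T - win + 1), step):
        sl = slice(start, min(start + win, T))
        sub_mask = None if mask is None else mask[sl]
        res = delayed_correlation(
            series_i[sl],
            series_j[sl],
            fps,
            mask=sub_mask,
            max_lag=max_lag,
            channel=channel,
            min_overlap=min_overlap,
            pair=pair,
        )
        if res.defined:
            delays.append(res.delay_s)
            peaks.append(res.peak_corr)
            n_total += res.n_valid_frames
    if not delays:
        return DyadDelayResult(pair, channel, None, None, 0)
    return DyadDelayResult(
        pair, channel, float(np.mean(delays)), float(np.mean(peaks)), n_total
    )


def build_network(results: list[DyadDelayResult]) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Directed leadership network from dyadic delays.

    For each dyad with a defined non-zero delay, an edge runs from the
    earlier (leading) fish to the later one, weighted by |tau*| in seconds;
    zero delays contribute no edge.  Also returns a per-fish summary with
    out-degree, in-degree, net leading (out - in) and mean lead delay.
    """
    g = nx.DiGraph()
    for res in results:
        i, j = res.pair
        g.add_node(i)
        g.add_node(j)
        if not res.defined or res.delay_s == 0:
            continue
        leader, follower = (i, j) if res.delay_s > 0 else (j, i)
        g.add_edge(
            leader,
            follower,
            delay_s=abs(res.delay_s),
            peak_corr=res.peak_corr,
            channel=res.channel,
        )
    rows = []
    for node in g.nodes:
        out_d = g.out_degree(node)
        in_d = g.in_degree(node)
        lead_delays = [d["delay_s"] for _, _, d in g.out_edges(node, data=True)]
        rows.append(
            {
                "id": node,
                "out_degree": out_d,
                "in_degree": in_d,
                "net_leading": out_d - in_d,
                "mean_lead_delay_s": float(np.mean(lead_delays)) if lead_delays else np.nan,
            }
        )
    return g, pd.DataFrame(rows)


def analyse_group(
    group: GroupTrajectory,
    member_kin: list[KinematicsSeries],
    *,
    channel: str = "speed",
    max_lag: int = DEFAULT_MAX_LAG,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    windowed: bool = False,
    window_s: float = 30.0,
    differenced: bool = False,
) -> tuple[nx.DiGraph, pd.DataFrame, list[DyadDelayResult]]:
    """Dyadic delays and the leadership network for a whole group.

    ``channel`` is "speed" (Pearson on the speed series; first-differenced
    when ``differenced``) or "direction" (mean heading-difference cosine).
    """
    bl = group.body_length
    results = []
    for a in range(group.n):
        for b in range(a + 1, group.n):
            ti, tj = group.trajectories[a], group.trajectories[b]
            ki, kj = member_kin[a], member_kin[b]
            mask = eligible_frames(
                ti.positions, tj.positions, ki.speed, kj.speed, bl
            )
            if channel == "speed":
                si, sj = ki.speed, kj.speed
                if differenced:
                    si = np.diff(si, append=np.nan)
                    sj = np.diff(sj, append=np.nan)
            else:
                si, sj = ki.heading, kj.heading
            fn = windowed_delay if windowed else delayed_correlation
            kwargs = dict(
                mask=mask,
                max_lag=max_lag,
                channel=channel,
                min_overlap=min_overlap,
                pair=(ti.individual_id, tj.individual_id),
            )
            if windowed:
                kwargs["window_s"] = window_s
            results.append(fn(si, sj, group.fps, **kwargs))
    graph, summary = build_network(results)
    return graph, summary, results
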