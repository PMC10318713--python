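"""Per-fix movement metrics: step length, residence time, day home range.

These three metrics form the observation vector of the behavioural-state
hidden Markov model:

DIST
    Euclidean distance (m) between successive fixes, assigned to the
    interval's starting fix.
RT100
    Residence time (h) within a 100 m radius of the fix: forward plus
    backward time along the track before the animal leaves the circle for
    longer than a gap tolerance (default 2 h, the nominal fix interval;
    excursions of exactly the tolerance do not stop accumulation).  Circle
    crossing times between fixes are linearly interpolated on the
    distance-to-centre series.
HR
    Day home range (ha): area of a 95% minimum convex polygon over all fixes
    within a 24-h window centred on the fix.  The 95% MCP drops the
    floor(5% * n) fixes farthest from the window's arithmetic centroid
    before taking the convex hull; the 24-h window smooths diurnal
    variation in movement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

__all__ = [
    "step_length",
    "residence_time",
    "day_home_range",
    "compute_metrics",
    "mcp_area_ha",
    "mcp_trim",
]


def step_length(traj: pd.DataFrame) -> pd.Series:
    """Forward step length in metres; the last element is missing (nan)."""
    x = traj["x"].to_numpy()
    y = traj["y"].to_numpy()
    d = np.hypot(np.diff(x), np.diff(y))
    return pd.Series(np.append(d, np.nan), index=traj.index, name="dist")


def _crossing_time(t0: float, t1: float, d0: float, d1: float, radius: float) -> float:
    """Time at which the linearly interpolated distance series crosses radius."""
    return t0 + (radius - d0) / (d1 - d0) * (t1 - t0)


def _one_side_residence(
    t: np.ndarray, d: np.ndarray, i: int, radius: float, max_gap_h: float
) -> tuple[float, bool]:
    """Residence time (h) accumulated forward from fix ``i``.

    ``t`` is time in hours, ``d`` the distance of every fix to the circle
    centre (``d[i] == 0``).  Returns (hours, truncated-by-track-end flag).
    Call with reversed arrays for the backward direction.
    """
    n = len(t)
    j = i
    while True:
        if j == n - 1:
            return t[n - 1] - t[i], True  # track ended while qualifying
        if d[j] <= radius and d[j + 1] <= radius:
            j += 1
            continue
        # Exit: linear interpolation of the distance series.
        t_exit = _crossing_time(t[j], t[j + 1], d[j], d[j + 1], radius)
        # Scan for re-entry.
        k = j + 1
        while k < n - 1 and not (d[k] > radius and d[k + 1] <= radius):
            k += 1
        if k >= n - 1:
            # Never re-enters within the data.
            if t[n - 1] - t_exit > max_gap_h:
                return t_exit - t[i], False  # exit already disqualifying
            return t_exit - t[i], True  # unknown: truncated
        t_entry = _crossing_time(t[k], t[k + 1], d[k], d[k + 1], radius)
        if t_entry - t_exit > max_gap_h:
            return t_exit - t[i], False
        j = k + 1


def residence_time(
    traj: pd.DataFrame, radius: float = 100.0, max_gap_h: float = 2.0
) -> tuple[pd.Series, pd.Series]:
    """RT within ``radius`` m of each fix, in hours.

    Returns (rt series, truncated flags).  A flag marks fixes whose forward
    or backward accumulation was cut by the track end before an excursion
    longer than ``max_gap_h`` resolved it.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    t = pd.DatetimeIndex(traj["timestamp"]).asi8 / 3.6e12  # hours
    n = len(traj)
    rt = np.zeros(n)
    trunc = np.zeros(n, dtype=bool)
    tr = -t[::-1]  # reversed, re-increasing
    for i in range(n):
        d = np.hypot(x - x[i], y - y[i])
        fwd, f_tr = _one_side_residence(t, d, i, radius, max_gap_h)
        bwd, b_tr = _one_side_residence(tr, d[::-1], n - 1 - i, radius, max_gap_h)
        rt[i] = fwd + bwd
        trunc[i] = f_tr or b_tr
    return (
        pd.Series(rt, index=traj.index, name="rt100"),
        pd.Series(trunc, index=traj.index, name="rt_truncated"),
    )


def mcp_trim(xy: np.ndarray, level: float) -> np.ndarray:
    """Keep-mask of the ``level`` MCP trim.

    Drops the floor((1-level)*n) points farthest from the arithmetic
    centroid; among distance ties the later point (by input order, i.e.
    later timestamp) is removed first, so earlier fixes are retained.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    keep = np.ones(n, dtype=bool)
    m = int(np.floor((1.0 - level) * n))
    if m > 0:
        centroid = xy.mean(axis=0)
        dist = np.hypot(*(xy - centroid).T)
        drop = sorted(range(n), key=lambda i: (-dist[i], -i))[:m]
        keep[drop] = False
    return keep


def mcp_area_ha(xy: np.ndarray, level: float = 0.95) -> float:
    """Area (ha) of the ``level`` minimum convex polygon over points ``xy``.

    Fewer than three distinct retained points give area 0 (degenerate hull).
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 0:
        return 0.0
    pts = np.unique(xy[mcp_trim(xy, level)], axis=0)
    if len(pts) < 3:
        return 0.0
    return MultiPoint(pts).convex_hull.area / 1e4


def day_home_range(
    traj: pd.DataFrame, window_h: float = 24.0, mcp_level: float = 0.95
) -> tuple[pd.Series, pd.Series]:
    """Rolling-window MCP area (ha) centred on each fix.

    Returns (hr series, degenerate flags); a flag marks windows whose hull
    collapsed (fewer than three distinct retained points).
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    xy = traj[["x", "y"]].to_numpy(dtype=float)
    t = pd.DatetimeIndex(traj["timestamp"]).asi8 / 3.6e12  # hours
    n = len(traj)
    half = window_h / 2.0
    hr = np.zeros(n)
    degen = np.zeros(n, dtype=bool)
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    for i in range(n):
        pts = xy[lo[i] : hi[i]]
        area = mcp_area_ha(pts, level=mcp_level)
        hr[i] = area
        if area == 0.0:
            degen[i] = True
    return (
        pd.Series(hr, index=traj.index, name="hr"),
        pd.Series(degen, index=traj.index, name="hr_degenerate"),
    )


def compute_metrics(
    traj: pd.DataFrame,
    radius: float = 100.0,
    max_gap_h: float = 2.0,
    window_h: float = 24.0,
    mcp_level: float = 0.95,
) -> pd.DataFrame:
    """Compute the full (DIST, RT100, HR) observation table for one animal.

    The final fix's missing DIST is imputed with the preceding value so the
    HMM sees a complete series; the imputation is flagged in
    ``dist_imputed``.
    """
    out = pd.DataFrame(
        {
            "animal_id": traj["animal_id"].to_numpy(),
            "timestamp": traj["timestamp"].to_numpy(),
        },
        index=traj.index,
    )
    dist = step_length(traj)
    imputed = dist.isna()
    dist = dist.ffill()
    rt, rt_trunc = residence_time(traj, radius=radius, max_gap_h=max_gap_h)
    hr, hr_degen = day_home_range(traj, window_h=window_h, mcp_level=mcp_level)
    out["dist"] = dist
    out["rt100"] = rt
    out["hr"] = hr
    out["dist_imputed"] = imputed
    out["rt_truncated"] = rt_trunc
    out["hr_degenerate"] = hr_degen
    return out
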