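"""GPS error screening.

Three rules, applied in order, remove erroneous collar fixes:

1. drop fixes classified as 2D (position solved from fewer than four
   satellites);
2. drop fixes whose incoming travel speed exceeds a hard maximum
   (default 5 km/h — beyond a plausible sustained rate for a ewe);
3. drop "spike" fixes whose incoming AND outgoing speeds exceed a lower
   threshold (default 2 km/h) while the cosine of the turning angle is below
   -0.97, the out-and-back geometry of a positional artefact.

Removing a spike changes the speeds of its neighbours, so rules 2–3 are
iterated on the surviving sequence until a full pass removes nothing.  The
first and last fix of the surviving series are never removed by rules 2–3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningReport",
    "incoming_speed",
    "outgoing_speed",
    "turn_cosine",
    "screen_fixes",
]


@dataclass
class ScreeningReport:
    n_input: int
    n_removed_by_rule: dict[str, int] = field(
        default_factory=lambda: {"2d": 0, "speed": 0, "spike": 0}
    )
    removed_indices: list[int] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.n_removed_by_rule.values())

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def _dt_hours(traj: pd.DataFrame) -> np.ndarray:
    t = traj["timestamp"].to_numpy()
    return np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0


def _step_lengths(traj: pd.DataFrame) -> np.ndarray:
    dx = np.diff(traj["x"].to_numpy())
    dy = np.diff(traj["y"].to_numpy())
    return np.hypot(dx, dy)


def _speeds_kmh(traj: pd.DataFrame) -> np.ndarray:
    """Speed of each segment i -> i+1 in km/h; length n-1."""
    dt = _dt_hours(traj)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return _step_lengths(traj) / 1000.0 / dt


def _turn_cosines(traj: pd.DataFrame) -> np.ndarray:
    """Cosine of the turning angle at each interior fix; length n, nan at ends.

    The turn at fix i is the angle between the incoming vector p[i-1]->p[i]
    and the outgoing vector p[i]->p[i+1]; the cosine is their normalized dot
    product.  Zero-length steps leave the cosine undefined (nan).
    """
    x = traj["x"].to_numpy()
    y = traj["y"].to_numpy()
    n = len(x)
    cos = np.full(n, np.nan)
    ux, uy = np.diff(x), np.diff(y)  # segment vectors, length n-1
    norms = np.hypot(ux, uy)
    with np.errstate(invalid="ignore", divide="ignore"):
        dot = ux[:-1] * ux[1:] + uy[:-1] * uy[1:]
        denom = norms[:-1] * norms[1:]
        c = np.where(denom > 0, dot / denom, np.nan)
    cos[1 : n - 1] = np.clip(c, -1.0, 1.0)
    return cos


def incoming_speed(traj: pd.DataFrame, i: int) -> float:
    """Speed (km/h) of the segment arriving at fix ``i``. Requires i >= 1."""
    if i < 1:
        raise IndexError("incoming_speed requires a preceding fix")
    return float(_speeds_kmh(traj.iloc[i - 1 : i + 1])[0])


def outgoing_speed(traj: pd.DataFrame, i: int) -> float:
    """Speed (km/h) of the segment leaving fix ``i``. Requires i <= n-2."""
    if i >= len(traj) - 1:
        raise IndexError("outgoing_speed requires a following fix")
    return float(_speeds_kmh(traj.iloc[i : i + 2])[0])


def turn_cosine(traj: pd.DataFrame, i: int) -> float:
    """Turning-angle cosine at fix ``i`` (nan if a bounding step has length 0)."""
    if i < 1 or i >= len(traj) - 1:
        raise IndexError("turn_cosine requires both neighbours")
    return float(_turn_cosines(traj.iloc[i - 1 : i + 2])[1])


def screen_fixes(
    traj: pd.DataFrame,
    max_speed: float = 5.0,
    spike_speed: float = 2.0,
    cos_threshold: float = -0.97,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply the three screening rules; returns (clean trajectory, report).

    ``removed_indices`` refer to positional indices in the input trajectory.
    Raises if fewer than three fixes survive (downstream metrics would be
    undefined).
    """
    if len(traj) < 3:
        raise ValueError("screening requires at least 3 fixes")
    traj = traj.reset_index(drop=True)
    report = ScreeningReport(n_input=len(traj))
    orig_idx = np.arange(len(traj))

    # Rule 1: 2D fixes, once.
    is_2d = traj["fix_class"].astype(str).str.upper().eq("2D").to_numpy()
    report.n_removed_by_rule["2d"] = int(is_2d.sum())
    report.removed_indices.extend(orig_idx[is_2d].tolist())
    keep = ~is_2d
    cur = traj.loc[keep].reset_index(drop=True)
    cur_orig = orig_idx[keep]

    # Rules 2-3 to a fixed point.
    while True:
        if len(cur) < 3:
            raise ValueError("fewer than 3 fixes survived screening")
        speeds = _speeds_kmh(cur)  # segment i -> i+1
        n = len(cur)
        incoming = np.full(n, np.nan)
        incoming[1:] = speeds
        outgoing = np.full(n, np.nan)
        outgoing[:-1] = speeds
        interior = np.zeros(n, dtype=bool)
        interior[1:-1] = True

        rule2 = interior & (incoming > max_speed)
        if rule2.any():
            report.n_removed_by_rule["speed"] += int(rule2.sum())
            report.removed_indices.extend(cur_orig[rule2].tolist())
            cur = cur.loc[~rule2].reset_index(drop=True)
            cur_orig = cur_orig[~rule2]
            continue

        cos = _turn_cosines(cur)
        with np.errstate(invalid="ignore"):
            rule3 = (
                interior
                & (incoming > spike_speed)
                & (outgoing > spike_speed)
                & (cos < cos_threshold)
            )
        if rule3.any():
            report.n_removed_by_rule["spike"] += int(rule3.sum())
            report.removed_indices.extend(cur_orig[rule3].tolist())
            cur = cur.loc[~rule3].reset_index(drop=True)
            cur_orig = cur_orig[~rule3]
            continue
        break

    report.removed_indices.sort()
    return cur, report
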