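"""Readers and writers for the pipeline's delimited-text formats.

Collar CSV: one row per fix with columns ``animal_id, timestamp, x, y,
fix_class``; timestamps ISO-8601 UTC, coordinates projected metres, comma
separation, '.' decimal, no quoting of numerics.
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = [
    "read_collar_csv",
    "write_collar_csv",
    "read_metrics_csv",
    "write_metrics_csv",
]

logger = logging.getLogger("lambwatch")

COLLAR_COLUMNS = ("animal_id", "timestamp", "x", "y", "fix_class")


def read_collar_csv(path) -> dict[str, pd.DataFrame]:
    """Read a collar CSV into per-animal trajectories.

    Rows are grouped by ``animal_id`` and sorted by timestamp (out-of-order
    input is accepted with a logged notice).  Missing columns, unparseable
    timestamps, and duplicate (animal, timestamp) fixes raise with the
    offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = set(COLLAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"collar CSV missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(ts.index[ts.isna()][0]) + 1
        raise ValueError(f"unparseable timestamp at row {row}")
    df = df.assign(timestamp=ts)
    dup = df.duplicated(subset=["animal_id", "timestamp"], keep=False)
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValueError(f"duplicate fix for an animal at row {row}")
    out: dict[str, pd.DataFrame] = {}
    for aid, grp in df.groupby("animal_id", sort=True):
        if not grp["timestamp"].is_monotonic_increasing:
            logger.info("collar CSV: fixes for %s were out of order; sorted", aid)
        out[str(aid)] = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)[
            list(COLLAR_COLUMNS)
        ]
    return out


def write_collar_csv(trajs, path) -> None:
    """Write one or many trajectories to a collar CSV (ISO-8601 UTC timestamps)."""
    if isinstance(trajs, pd.DataFrame):
        trajs = [trajs]
    elif isinstance(trajs, dict):
        trajs = list(trajs.values())
    df = pd.concat(trajs, ignore_index=True)[list(COLLAR_COLUMNS)].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df.to_csv(path, index=False)


def write_metrics_csv(metrics, path) -> None:
    """Write metric tables (single table, list, or dict of them) to CSV."""
    if isinstance(metrics, pd.DataFrame):
        metrics = [metrics]
    elif isinstance(metrics, dict):
        metrics = list(metrics.values())
    df = pd.concat(metrics, ignore_index=True).copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df.to_csv(path, index=False)


def read_metrics_csv(path) -> dict[str, pd.DataFrame]:
    """Read a metrics CSV back into per-animal tables keyed by animal_id."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return {
        str(aid): grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        for aid, grp in df.groupby("animal_id", sort=True)
    }
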