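"""End-to-end pipeline driver.

Runs the full analysis on a fully synthetic herd (or on collar CSVs):
screening -> movement metrics -> HMM fit on parturient animals -> Viterbi
decoding -> lambing calls -> optional habitat stages (LSD and per-status
RSF over a simulated landscape).  Every intermediate is written to the
output directory along with a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .habitat import (
    build_lsd_table,
    build_rsf_table,
    compare_selection,
    fit_random_intercept_logistic,
    pool_and_standardize,
    pooled_mcp,
)
from .hmm import fit_hmm, label_states, viterbi
from .io import write_collar_csv, write_metrics_csv
from .landscape import simulate_landscape
from .metrics import compute_metrics
from .parturition import detect_lambing
from .screening import screen_fixes
from .simulate import SimConfig, simulate_herd

logger = logging.getLogger("lambwatch")


@dataclasses.dataclass
class PipelineConfig:
    """Parameters of a fully synthetic pipeline run (defaults per stage docs)."""

    n_parturient: int = 13
    n_nonparturient: int = 8
    seed: int = 0
    p_2d: float = 0.01
    p_spike: float = 0.005
    max_speed_kmh: float = 5.0
    spike_speed_kmh: float = 2.0
    cos_threshold: float = -0.97
    rt_radius_m: float = 100.0
    rt_max_gap_h: float = 2.0
    hr_window_h: float = 24.0
    mcp_level: float = 0.95
    n_restarts: int = 5
    detect_window_h: float = 48.0
    detect_threshold: float = 0.5
    lsd_span_days: float = 15.0
    rsf_ratio: int = 10
    decay_range_m: float = 500.0
    habitat: bool = True
    landscape_extent_km: float = 8.0
    landscape_resolution_m: float = 50.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "created": dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
        "config": dataclasses.asdict(config),
        "artifacts": {},
    }

    def save(name: str, path: Path) -> None:
        manifest["artifacts"][name] = path.name

    base = SimConfig(p_2d=config.p_2d, p_spike=config.p_spike)
    trajs, truths = simulate_herd(
        config.n_parturient, config.n_nonparturient, seed=config.seed, base_config=base
    )
    write_collar_csv(trajs, out / "collar_raw.csv")
    save("collar_raw", out / "collar_raw.csv")

    clean: dict[str, pd.DataFrame] = {}
    reports = {}
    for aid, traj in trajs.items():
        clean[aid], rep = screen_fixes(
            traj,
            max_speed=config.max_speed_kmh,
            spike_speed=config.spike_speed_kmh,
            cos_threshold=config.cos_threshold,
        )
        reports[aid] = {
            "n_input": rep.n_input,
            "n_removed_by_rule": rep.n_removed_by_rule,
            "fraction_removed": rep.fraction_removed,
        }
    write_collar_csv(clean, out / "collar_clean.csv")
    save("collar_clean", out / "collar_clean.csv")
    (out / "screening_report.json").write_text(json.dumps(reports, indent=2))
    save("screening_report", out / "screening_report.json")

    metric_sets = {
        aid: compute_metrics(
            traj,
            radius=config.rt_radius_m,
            max_gap_h=config.rt_max_gap_h,
            window_h=config.hr_window_h,
            mcp_level=config.mcp_level,
        )
        for aid, traj in clean.items()
    }
    write_metrics_csv(metric_sets, out / "metrics.csv")
    save("metrics", out / "metrics.csv")

    part_ids = [a for a in metric_sets if a.startswith("P")]
    model = label_states(
        fit_hmm(
            [metric_sets[a] for a in part_ids],
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
    )
    model.to_json(out / "model.json")
    save("model", out / "model.json")

    states = {aid: viterbi(model, m) for aid, m in metric_sets.items()}
    pd.concat(states.values(), ignore_index=True).to_csv(out / "states.csv", index=False)
    save("states", out / "states.csv")

    calls = {}
    rows = []
    for aid, st in states.items():
        call = detect_lambing(
            st, window_h=config.detect_window_h, threshold=config.detect_threshold
        )
        calls[aid] = call
        rows.append(
            {
                "animal_id": aid,
                "detected": call.detected,
                "lambing_date": call.lambing_date,
                "proportion": call.window_proportion,
            }
        )
    pd.DataFrame(rows).to_csv(out / "calls.csv", index=False)
    save("calls", out / "calls.csv")

    if config.habitat:
        ext = config.landscape_extent_km * 1000.0
        # Centre the landscape on the pooled fixes so every fix is on-raster.
        all_fixes = pd.concat(clean.values(), ignore_index=True)
        cx, cy = all_fixes["x"].mean(), all_fixes["y"].mean()
        span = max(
            all_fixes["x"].max() - all_fixes["x"].min(),
            all_fixes["y"].max() - all_fixes["y"].min(),
            ext,
        )
        half = (
            np.ceil(span * 0.75 / config.landscape_resolution_m)
            * config.landscape_resolution_m
        )
        stack = simulate_landscape(
            extent=(cx - half, cy - half, cx + half, cy + half),
            resolution=config.landscape_resolution_m,
            seed=config.seed,
        )
        for name, raster in stack.layers.items():
            raster.to_ascii(out / f"raster_{name}.asc")
        save("rasters", out / "raster_*.asc")

        lsd_tables = [
            build_lsd_table(
                clean[a], calls[a], stack,
                span_days=config.lsd_span_days, decay_range_m=config.decay_range_m,
            )
            for a in part_ids
            if calls[a].detected
        ]
        if len(lsd_tables) >= 2:
            lsd = pool_and_standardize(lsd_tables)
            lsd.to_csv(out / "lsd_table.csv", index=False)
            save("lsd_table", out / "lsd_table.csv")
            try:
                lsd_fit = fit_random_intercept_logistic(lsd)
            except ValueError as exc:
                # A handful of wandering animals can separate pre/post
                # spatially; record the degenerate design instead of failing.
                logger.warning("LSD fit skipped: %s", exc)
                manifest["artifacts"]["lsd_fit"] = f"skipped: {exc}"
            else:
                lsd_fit.params.to_csv(out / "lsd_fit.csv")
                save("lsd_fit", out / "lsd_fit.csv")

        hr = pooled_mcp(all_fixes, level=config.mcp_level)
        (out / "home_range.wkt").write_text(hr.wkt)
        save("home_range", out / "home_range.wkt")
        fits = {}
        for status, prefix in (("parturient", "P"), ("nonparturient", "N")):
            used = all_fixes[all_fixes["animal_id"].str.startswith(prefix)]
            if used["animal_id"].nunique() < 2:
                continue
            tab = pool_and_standardize(
                [
                    build_rsf_table(
                        used, stack, ratio=config.rsf_ratio,
                        seed=config.seed, home_range=hr,
                        decay_range_m=config.decay_range_m,
                    )
                ]
            )
            try:
                fit = fit_random_intercept_logistic(tab)
            except ValueError as exc:
                logger.warning("RSF fit (%s) skipped: %s", status, exc)
                manifest["artifacts"][f"rsf_fit_{status}"] = f"skipped: {exc}"
                continue
            fit.params.to_csv(out / f"rsf_fit_{status}.csv")
            save(f"rsf_fit_{status}", out / f"rsf_fit_{status}.csv")
            fits[status] = fit
        if len(fits) == 2:
            comparison = compare_selection(fits["parturient"], fits["nonparturient"])
            comparison.to_csv(out / "rsf_comparison.csv")
            save("rsf_comparison", out / "rsf_comparison.csv")
    else:
        logger.info("habitat stages skipped (habitat=False in config)")
        manifest["artifacts"]["habitat"] = "skipped"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
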