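"""End-to-end analysis pipeline: project -> segment -> classify -> MSD -> report.

Driven by a small YAML/JSON config that either names input CSV files
(tracks, axes, optional obstacles and bleach traces) or selects a
synthetic preset.  Every stage logs its in/out record counts, all outputs
are CSV, and a JSON manifest records the package version, seed and
parameters so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .encounters import outcome_fractions, score_obstacle_encounters
from .geometry import project_onto_axis
from .io import read_axes, read_obstacles, read_tracks, read_traces
from .msd import diffusion_coeff, loglog_slope, msd_internal
from .photobleaching import estimate_copies, fit_steps
from .segmentation import SegmentationParams, classify_track, population_stats, segment_runs
from .synthetic import MotionModel, SimConfig, default_axis, simulate_population, simulate_track

log = logging.getLogger("rnptrack")

PRESETS = ("fig2-synthetic", "population-synthetic")


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    text = Path(config).read_text()
    return yaml.safe_load(text) or {}


def _preset_tracks(name: str, seed: int):
    """Synthetic input presets; returns (trajectories, axis, chamber_ids)."""
    if name == "fig2-synthetic":
        cfg = SimConfig(frame_rate=15.0, n_frames=300, seed=seed)
        axis = default_axis(cfg)
        rngs = np.random.SeedSequence(seed).spawn(40)
        trajs = []
        for i, ss in enumerate(rngs):
            model = (
                MotionModel(mode="processive", velocity=-1200.0)
                if i < 20
                else MotionModel(mode="diffusive", diffusion_coeff=5000.0)
            )
            traj, _ = simulate_track(
                model, cfg, rng=np.random.default_rng(ss), track_id=f"track{i}"
            )
            trajs.append(traj)
        return trajs, axis, [0] * len(trajs)
    if name == "population-synthetic":
        trajs, chambers = [], []
        for c in range(10):
            cfg = SimConfig(frame_rate=15.0, n_frames=300, seed=seed + c)
            for traj, _ in simulate_population(60, cfg, processive_fraction=0.24):
                traj.track_id = f"c{c}_{traj.track_id}"
                trajs.append(traj)
                chambers.append(c)
        return trajs, default_axis(SimConfig(seed=seed)), chambers
    raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")


def run_pipeline(config, out_dir) -> dict:
    """Run the full pipeline and write CSV outputs plus a JSON manifest.

    Returns the report dictionary (also written to ``report.json``).  An
    empty input yields an empty report with ``"empty": true`` rather than
    an error.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    params = cfg.get("params", {})
    seg_params = SegmentationParams(
        run_cutoff=float(params.get("run_cutoff_nm", 22.0)),
        pixel_size=float(params.get("pixel_size_nm", 105.0)),
    )
    report: dict = {"seed": seed, "version": __version__, "stages": {}}

    chamber_ids = None
    if "preset" in cfg:
        trajs, axis, chamber_ids = _preset_tracks(cfg["preset"], seed)
        axes = [axis]
    else:
        inputs = cfg.get("inputs", {})
        trajs = read_tracks(inputs["tracks"]) if "tracks" in inputs else []
        axes = read_axes(inputs["axes"]) if "axes" in inputs else []
    log.info("input: %d tracks, %d axes", len(trajs), len(axes))
    report["stages"]["input"] = {"tracks": len(trajs), "axes": len(axes)}

    if not trajs:
        report["empty"] = True
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return report
    if not axes:
        raise ValueError("no microtubule axes supplied")

    # project each track onto the best-fitting axis (minimum mean off-axis residual)
    onaxis = []
    for traj in trajs:
        candidates = [project_onto_axis(traj, ax) for ax in axes]
        onaxis.append(min(candidates, key=lambda t: float(np.mean(t.residual))))

    tables = [segment_runs(t, seg_params) for t in onaxis]
    for t in tables:
        classify_track(t, seg_params)
    run_rows = [
        {
            "track_id": t.track_id,
            "classification": t.classification,
            "direction": r.direction,
            "length_nm": r.length,
            "duration_s": r.duration,
            "velocity_nm_s": r.velocity,
            "termination": r.termination,
        }
        for t in tables
        for r in t.runs
    ]
    pd.DataFrame(
        run_rows,
        columns=[
            "track_id",
            "classification",
            "direction",
            "length_nm",
            "duration_s",
            "velocity_nm_s",
            "termination",
        ],
    ).to_csv(out / "runs.csv", index=False)
    log.info("segmentation: %d tracks -> %d runs", len(tables), len(run_rows))
    report["stages"]["segmentation"] = {"tracks": len(tables), "runs": len(run_rows)}

    pop = population_stats(tables, chamber_ids, seg_params)
    pop.per_chamber.to_csv(out / "chambers.csv", index=False)
    report["population"] = {
        "unidirectional_fraction_mean": pop.fraction_mean,
        "unidirectional_fraction_sem": pop.fraction_sem,
    }

    msd_rows = []
    for t in onaxis:
        if t.n_frames < 8:
            continue
        m = msd_internal(t, float(params.get("max_lag_fraction", 0.25)))
        try:
            sl = loglog_slope(m)
        except ValueError:
            continue
        d = diffusion_coeff(m)
        msd_rows.append(
            {
                "track_id": t.track_id,
                "loglog_slope": sl.slope,
                "slope_se": sl.stderr,
                "D_nm2_s": d.D,
            }
        )
    msd_df = pd.DataFrame(msd_rows, columns=["track_id", "loglog_slope", "slope_se", "D_nm2_s"])
    msd_df.to_csv(out / "msd.csv", index=False)
    if not msd_df.empty:
        cls = {t.track_id: t.classification for t in tables}
        msd_df["classification"] = msd_df["track_id"].map(cls)
        slope_table = (
            msd_df.groupby("classification")["loglog_slope"].agg(["mean", "sem", "count"]).reset_index()
        )
        slope_table.to_csv(out / "msd_slopes_by_class.csv", index=False)
        report["msd_slopes"] = {
            str(r["classification"]): float(r["mean"]) for _, r in slope_table.iterrows()
        }
    report["stages"]["msd"] = {"tracks": len(msd_rows)}

    if "inputs" in cfg and "obstacles" in cfg.get("inputs", {}):
        maps = read_obstacles(cfg["inputs"]["obstacles"])
        records = []
        for t, tab in zip(onaxis, tables):
            if t.mt_id in maps:
                records.extend(score_obstacle_encounters(t, tab, maps[t.mt_id]))
        enc_df = pd.DataFrame(
            [
                {
                    "track_id": r.track_id,
                    "obstacle_index": r.obstacle_index,
                    "approach": r.approach,
                    "outcome": r.outcome,
                    "frame": r.frame,
                    "censored": r.censored,
                }
                for r in records
            ]
        )
        enc_df.to_csv(out / "encounters.csv", index=False)
        report["encounters"] = outcome_fractions(records).to_dict()
        report["stages"]["encounters"] = {"records": len(records)}

    if "inputs" in cfg and "traces" in cfg.get("inputs", {}):
        traces = read_traces(cfg["inputs"]["traces"])
        fits = [fit_steps(v) for v in traces.values()]
        est = estimate_copies(
            fits,
            label_fraction=float(params.get("label_fraction", 0.49)),
            subunits_per_motor=int(params.get("subunits_per_motor", 2)),
        )
        report["photobleaching"] = {
            "mean_steps": est.mean_steps,
            "subunit_copies": est.subunit_copies,
            "motors": est.motors,
            "n_traces": est.n_traces,
        }
        report["stages"]["photobleaching"] = {"traces": len(traces)}

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest = {"seed": seed, "version": __version__, "params": params, "config": {k: v for k, v in cfg.items() if k != "params"}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return report
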