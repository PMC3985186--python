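"""CSV readers/writers for tracks, axes, obstacles, bleach traces and ground truth.

All files are plain CSV with a header row; lengths in nm, times in
seconds.  Dialects:

* tracks:    ``track_id, frame, time_s, x_nm, y_nm``
* axes:      ``mt_id, minus_x_nm, minus_y_nm, plus_x_nm, plus_y_nm``
* obstacles: ``mt_id, start_nm, end_nm, stationary``
* traces:    ``trace_id, frame, intensity``

Round-trip guarantee: ``read(write(x)) == x`` at the numeric precision of
the file format.  Malformed inputs (missing columns, duplicated
``(track_id, frame)`` rows, non-monotone frames) raise with the offending
row identified.

Coordinates exported by tracking software (e.g. TrackMate spot tables)
can be converted by renaming columns to the track dialect above and
converting positions to nm; see ``convert_spot_table``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .encounters import ObstacleMap
from .geometry import MicrotubuleAxis, Trajectory

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_axes",
    "write_axes",
    "read_obstacles",
    "write_obstacles",
    "read_traces",
    "write_traces",
    "write_ground_truth",
    "convert_spot_table",
]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_nm", "y_nm"]
AXIS_COLUMNS = ["mt_id", "minus_x_nm", "minus_y_nm", "plus_x_nm", "plus_y_nm"]
OBSTACLE_COLUMNS = ["mt_id", "start_nm", "end_nm", "stationary"]
TRACE_COLUMNS = ["trace_id", "frame", "intensity"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_tracks(path) -> list[Trajectory]:
    """Read a track table into a list of trajectories.

    The frame interval of each track is inferred from the median spacing
    of its ``time_s`` column.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty track table")
        return []
    _require_columns(df, TRACK_COLUMNS, path)
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: duplicated (track_id, frame) at data row {row}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_index()
        frames = g["frame"].to_numpy()
        if not (np.diff(frames) > 0).all():
            bad = int(g.index[np.flatnonzero(np.diff(frames) <= 0)[0] + 1])
            raise ValueError(f"{path}: non-monotone frames for track {tid!r} at data row {bad}")
        times = g["time_s"].to_numpy(float)
        dt = float(np.median(np.diff(times) / np.diff(frames)))
        tracks.append(
            Trajectory(
                track_id=str(tid),
                frames=frames,
                x=g["x_nm"].to_numpy(float),
                y=g["y_nm"].to_numpy(float),
                frame_interval=dt,
            )
        )
    return tracks


def write_tracks(tracks: list[Trajectory], path) -> None:
    rows = [
        pd.DataFrame(
            {
                "track_id": t.track_id,
                "frame": t.frames,
                "time_s": t.times,
                "x_nm": t.x,
                "y_nm": t.y,
            }
        )
        for t in tracks
    ]
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)


def read_axes(path) -> list[MicrotubuleAxis]:
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty axis table")
        return []
    _require_columns(df, AXIS_COLUMNS, path)
    return [
        MicrotubuleAxis(
            mt_id=str(r.mt_id),
            minus_end=(float(r.minus_x_nm), float(r.minus_y_nm)),
            plus_end=(float(r.plus_x_nm), float(r.plus_y_nm)),
        )
        for r in df.itertuples()
    ]


def write_axes(axes: list[MicrotubuleAxis], path) -> None:
    pd.DataFrame(
        [
            {
                "mt_id": a.mt_id,
                "minus_x_nm": a.minus_end[0],
                "minus_y_nm": a.minus_end[1],
                "plus_x_nm": a.plus_end[0],
                "plus_y_nm": a.plus_end[1],
            }
            for a in axes
        ],
        columns=AXIS_COLUMNS,
    ).to_csv(path, index=False)


def read_obstacles(path) -> dict[str, ObstacleMap]:
    """Read obstacle puncta grouped per microtubule."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty obstacle table")
        return {}
    _require_columns(df, OBSTACLE_COLUMNS, path)
    out = {}
    for mt_id, g in df.groupby("mt_id", sort=True):
        out[str(mt_id)] = ObstacleMap(
            mt_id=str(mt_id),
            intervals=list(zip(g["start_nm"].astype(float), g["end_nm"].astype(float))),
            stationary=g["stationary"].astype(bool).tolist(),
        )
    return out


def write_obstacles(maps: dict[str, ObstacleMap], path) -> None:
    rows = []
    for m in maps.values():
        for (a, b), st in zip(m.intervals, m.stationary):
            rows.append({"mt_id": m.mt_id, "start_nm": a, "end_nm": b, "stationary": st})
    pd.DataFrame(rows, columns=OBSTACLE_COLUMNS).to_csv(path, index=False)


def read_traces(path) -> dict[str, np.ndarray]:
    """Read photobleaching intensity traces keyed by trace id."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty trace table")
        return {}
    _require_columns(df, TRACE_COLUMNS, path)
    out = {}
    for tid, g in df.groupby("trace_id", sort=True):
        out[str(tid)] = g.sort_values("frame")["intensity"].to_numpy(float)
    return out


def write_traces(traces: dict[str, np.ndarray], path) -> None:
    rows = [
        pd.DataFrame({"trace_id": tid, "frame": np.arange(len(v)), "intensity": v})
        for tid, v in traces.items()
    ]
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TRACE_COLUMNS)
    df.to_csv(path, index=False)


def write_ground_truth(gts: list, path) -> None:
    """Write simulation ground truth as a JSON sidecar."""
    from dataclasses import asdict

    payload = [asdict(g) for g in gts]
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def convert_spot_table(path):
    """Stub converter for proprietary tracker exports.

    Not implemented: export your spot table with columns convertible to
    ``track_id, frame, time_s, x_nm, y_nm`` (one row per spot per frame,
    positions in nm) and read it with :func:`read_tracks`.  Typical spot
    tables provide TRACK_ID, FRAME, POSITION_X/POSITION_Y (um or pixels) -
    rename the columns, convert positions to nm, and add ``time_s`` as
    frame times in seconds.
    """
    raise NotImplementedError(convert_spot_table.__doc__)
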