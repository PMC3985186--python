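"""Scoring of particle encounters with obstacles and microtubule ends.

Obstacle encounters are scored per approach run: whenever an above-cutoff
run carries the particle into the pixel-quantized interval occupied by a
static obstacle punctum, the encounter outcome is determined by the fate
of that run - it passes out the far side, reverses, pauses, or the track
ends there (detachment).  The chance-coincidence null overlays obstacle
layouts from an independent source on obstacle-free tracks and applies the
*same* scoring code path, so observed and null rates are directly
comparable.

End encounters are scored from residence of the particle within a
proximity zone at either microtubule end; a pause requires stationarity
for longer than one frame.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .geometry import OnAxisTrack
from .segmentation import MINUS, PLUS, RunTable

__all__ = [
    "ObstacleMap",
    "EncounterRecord",
    "EndEncounter",
    "score_obstacle_encounters",
    "simulate_null_encounters",
    "compare_outcomes",
    "score_end_encounters",
    "outcome_fractions",
    "mean_end_pause",
]


@dataclass
class ObstacleMap:
    """Static obstacle puncta on one microtubule.

    Each punctum occupies an interval ``(start_nm, end_nm)`` along the
    axis; only puncta flagged stationary over the acquisition are used for
    encounter scoring (diffusing puncta are excluded).  Overlapping
    intervals are merged with a warning.
    """

    mt_id: str
    intervals: list[tuple[float, float]]
    stationary: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.stationary is None:
            self.stationary = [True] * len(self.intervals)
        if len(self.stationary) != len(self.intervals):
            raise ValueError("stationary flags must match intervals")
        ivs = sorted(
            (tuple(map(float, iv)), st) for iv, st in zip(self.intervals, self.stationary)
        )
        merged: list[tuple[float, float]] = []
        flags: list[bool] = []
        for (a, b), st in ivs:
            if b < a:
                raise ValueError(f"obstacle interval reversed: ({a}, {b})")
            if merged and a < merged[-1][1]:
                warnings.warn(f"overlapping obstacle puncta on {self.mt_id!r} merged")
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                flags[-1] = flags[-1] and st
            else:
                merged.append((a, b))
                flags.append(st)
        self.intervals = merged
        self.stationary = flags

    @property
    def static_intervals(self) -> list[tuple[float, float]]:
        return [iv for iv, st in zip(self.intervals, self.stationary) if st]

    @property
    def n_puncta(self) -> int:
        return len(self.intervals)


@dataclass
class EncounterRecord:
    """Outcome of one particle-obstacle encounter."""

    track_id: str
    obstacle_index: int
    approach: str  # direction of the run preceding contact: "minus" | "plus"
    outcome: str | None  # reversal | pass | pause | detach; None if censored
    frame: int  # displacement index at which the approach run contacted the zone
    censored: bool = False


def _quantized_zone(
    interval: tuple[float, float], pixel_size: float, tolerance_px: int
) -> tuple[float, float]:
    a = np.floor(interval[0] / pixel_size) * pixel_size - tolerance_px * pixel_size
    b = np.ceil(interval[1] / pixel_size) * pixel_size + tolerance_px * pixel_size
    return float(a), float(b)


def score_obstacle_encounters(
    track: OnAxisTrack,
    runs: RunTable,
    obstacles: ObstacleMap,
    *,
    pixel_size: float = 105.0,
    tolerance_px: int = 1,
    acquisition_n_frames: int | None = None,
) -> list[EncounterRecord]:
    """Score every encounter of a segmented track with static obstacle puncta.

    An encounter opens when a run's path reaches a punctum's
    pixel-quantized interval (with +/- ``tolerance_px`` pixels of slack).
    Outcomes, with precedence reversal > detach > pause > pass:

    * ``pass`` - the run carries the particle out the far side;
    * ``reversal`` - the run terminates in the zone with a reversal, or
      pauses there for at most one frame and then reverses;
    * ``detach`` - the track ends in the zone before the acquisition ends;
    * ``pause`` - the run terminates in the zone with a pause.

    Runs that begin inside a zone are counted as fresh encounters unless
    they immediately follow a reversal (the bounce-back of an encounter
    already scored).  Repeated encounters of one particle with one
    obstacle are all counted.
    """
    records: list[EncounterRecord] = []
    zones = [
        _quantized_zone(iv, pixel_size, tolerance_px) for iv in obstacles.static_intervals
    ]
    if not zones:
        return records
    s = track.s
    last_frame_is_acq_end = (
        acquisition_n_frames is None or int(track.frames[-1]) >= acquisition_n_frames - 1
    )
    pause_at = {p.start: p for p in runs.pauses}
    run_at = {r.start: r for r in runs.runs}

    for ri, run in enumerate(runs.runs):
        prev_run = runs.runs[ri - 1] if ri > 0 else None
        sign = -1 if run.direction == MINUS else 1
        path = s[run.start : run.stop + 1]
        for zi, (a, b) in enumerate(zones):
            inside = (path >= a) & (path <= b)
            crossed = (path[0] < a and path[-1] > b) or (path[0] > b and path[-1] < a)
            if not inside.any() and not crossed:
                continue
            start_inside = a <= path[0] <= b
            if start_inside and prev_run is not None and prev_run.direction != run.direction:
                continue  # departing bounce-back of an encounter already scored
            end_pos = path[-1]
            far_exit = end_pos > b if sign > 0 else end_pos < a
            contact = run.start if start_inside else run.start + int(np.argmax(inside))
            if far_exit:
                outcome, censored = "pass", False
            elif run.termination == "reversal":
                outcome, censored = "reversal", False
            elif run.termination in ("detach",):
                outcome, censored = "detach", False
            elif run.termination in ("pause", "mt_end"):
                pause = pause_at.get(run.stop)
                nxt = run_at.get(run.stop + pause.n_frames) if pause is not None else None
                if (
                    pause is not None
                    and pause.n_frames <= 1
                    and nxt is not None
                    and nxt.direction != run.direction
                ):
                    outcome, censored = "reversal", False  # pause of <=1 frame then reversal
                elif pause is not None and run.stop + pause.n_frames == runs.n_displacements:
                    # track ends while paused in the zone
                    if last_frame_is_acq_end:
                        outcome, censored = "pause", True
                    else:
                        outcome, censored = "detach", False
                else:
                    outcome, censored = "pause", False
            else:  # end_of_acquisition: fate unresolved
                outcome, censored = None, True
            records.append(
                EncounterRecord(
                    track_id=track.track_id,
                    obstacle_index=zi,
                    approach=run.direction,
                    outcome=outcome,
                    frame=int(contact),
                    censored=censored,
                )
            )
    return records


def simulate_null_encounters(
    tracks_and_runs: list[tuple[OnAxisTrack, RunTable]],
    layouts: list[ObstacleMap],
    **score_kwargs,
) -> list[EncounterRecord]:
    """Chance-coincidence null: overlay independent obstacle layouts on
    obstacle-free tracks and score them with the identical code path.

    ``layouts`` (e.g. obstacle maps measured in a separate experiment, or
    generated by the simulator) are cycled over the supplied tracks.  The
    resulting outcome rates estimate how often reversals, pauses etc.
    would coincide with obstacle positions by chance alone.
    """
    if not layouts:
        raise ValueError("need at least one obstacle layout")
    records: list[EncounterRecord] = []
    for (track, runs), layout in zip(tracks_and_runs, itertools.cycle(layouts)):
        records.extend(score_obstacle_encounters(track, runs, layout, **score_kwargs))
    return records


def outcome_fractions(records: list[EncounterRecord]) -> pd.Series:
    """Fractions of resolved encounter outcomes; sums to 1 exactly."""
    outcomes = [r.outcome for r in records if r.outcome is not None]
    if not outcomes:
        return pd.Series(dtype=float)
    counts = pd.Series(outcomes).value_counts()
    return counts / counts.sum()


def compare_outcomes(
    observed: list[EncounterRecord],
    null: list[EncounterRecord],
    stratify_by_approach: bool = False,
) -> pd.DataFrame:
    """Contingency comparison of observed vs chance-coincidence outcomes.

    For each outcome category, builds the 2x2 table
    (outcome vs all others) x (observed vs null) and reports Fisher's
    exact two-sided p-value along with counts and fractions.
    """

    def _table(obs, nul):
        obs_o = [r.outcome for r in obs if r.outcome is not None]
        nul_o = [r.outcome for r in nul if r.outcome is not None]
        if not obs_o or not nul_o:
            raise ValueError("both observed and null must contain >=1 resolved encounter")
        rows = []
        for outcome in sorted(set(obs_o) | set(nul_o)):
            a = sum(o == outcome for o in obs_o)
            c = sum(o == outcome for o in nul_o)
            table = [[a, len(obs_o) - a], [c, len(nul_o) - c]]
            _, p = _stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "outcome": outcome,
                    "observed_count": a,
                    "observed_fraction": a / len(obs_o),
                    "null_count": c,
                    "null_fraction": c / len(nul_o),
                    "fisher_p": float(p),
                }
            )
        return rows

    if not stratify_by_approach:
        return pd.DataFrame(_table(observed, null))
    frames = []
    for direction in (MINUS, PLUS):
        obs_d = [r for r in observed if r.approach == direction]
        nul_d = [r for r in null if r.approach == direction]
        if not obs_d or not nul_d:
            continue
        df = pd.DataFrame(_table(obs_d, nul_d))
        df.insert(0, "approach", direction)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class EndEncounter:
    """Outcome of a particle encounter with a microtubule end."""

    track_id: str
    end: str  # "minus" | "plus"
    rnp_class: str | None  # classification of the particle's track
    outcome: str | None  # reversal | pause | detach; None if unresolved
    pause_s: float | None  # dwell duration at the end when a pause occurred
    censored: bool
    entry_frame: int


def score_end_encounters(
    track: OnAxisTrack,
    runs: RunTable,
    mt_length: float,
    *,
    end_threshold: float = 210.0,
    pause_min_s: float | None = None,
    acquisition_n_frames: int | None = None,
) -> list[EndEncounter]:
    """Score encounters of a track with the minus and plus microtubule ends.

    An encounter opens when the on-axis position comes within
    ``end_threshold`` nm (default two pixels) of ``s = 0`` (minus end) or
    ``s = mt_length`` (plus end).  The dwell in the end zone determines the
    outcome:

    * dwell longer than one frame (``pause_min_s``, default one frame
      interval) -> ``pause`` with its duration; the pause is censored when
      it is cut off by the end of acquisition;
    * brief contact followed by departure -> ``reversal``;
    * brief contact at which the track ends before acquisition end ->
      ``detach``.
    """
    dt = track.frame_interval
    if pause_min_s is None:
        pause_min_s = dt  # "stationary for longer than 1 frame"
    s = track.s
    n = s.size
    last_frame_is_acq_end = (
        acquisition_n_frames is None or int(track.frames[-1]) >= acquisition_n_frames - 1
    )
    encounters: list[EndEncounter] = []
    for end_name, in_zone in (
        (MINUS, s <= end_threshold),
        (PLUS, s >= mt_length - end_threshold),
    ):
        idx = np.flatnonzero(in_zone)
        if idx.size == 0:
            continue
        # contiguous residence spans
        breaks = np.flatnonzero(np.diff(idx) > 1)
        span_starts = np.concatenate([[0], breaks + 1])
        span_stops = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(span_starts, span_stops):
            first, last = int(idx[a]), int(idx[b])
            dwell = (last - first) * dt
            at_track_end = last == n - 1
            if dwell > pause_min_s:
                censored = at_track_end and last_frame_is_acq_end
                outcome = "pause"
            elif not at_track_end:
                outcome, censored = "reversal", False
            elif not last_frame_is_acq_end:
                outcome, censored = "detach", False
            else:
                outcome, censored = None, True  # brief contact cut by acquisition end
            encounters.append(
                EndEncounter(
                    track_id=track.track_id,
                    end=end_name,
                    rnp_class=runs.classification,
                    outcome=outcome,
                    pause_s=dwell if outcome == "pause" else None,
                    censored=censored,
                    entry_frame=first,
                )
            )
    return encounters


def mean_end_pause(
    encounters: list[EndEncounter], end: str = MINUS, include_censored: bool = False
) -> tuple[float, float, int]:
    """Mean +/- SEM of end-pause durations at the given end.

    Censored pauses (cut off by the end of acquisition) are excluded by
    default since they only bound the true dwell from below.
    """
    durations = [
        e.pause_s
        for e in encounters
        if e.end == end and e.outcome == "pause" and (include_censored or not e.censored)
    ]
    if not durations:
        raise ValueError(f"no qualifying pauses at the {end} end")
    arr = np.asarray(durations, float)
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem, int(arr.size)
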