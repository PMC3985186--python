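"""Run/pause/reversal segmentation of on-axis displacement series.

The segmentation follows a simple thresholded-displacement rule. With a
run cutoff of 22 nm (about twice the tracking accuracy of immobile
particles):

* a frame-to-frame displacement with ``|d| <= cutoff`` is a pause frame;
  pauses are maximal blocks of >=1 such frame;
* a run is a maximal block of consecutive same-sign displacements each
  with ``|d| > cutoff``; its length is the summed magnitude of those
  displacements, its duration the block's frame count times the frame
  interval, and its velocity length/duration;
* a reversal is scored between consecutive displacements ``d_i, d_{i+1}``
  when both exceed the cutoff and have opposite sign, i.e.
  ``|sign(d_i) - sign(d_{i+1})| = 2``.

Tracks are then classified as stationary (no motion beyond one pixel),
unidirectional (runs in one direction only) or bidirectional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import OnAxisTrack

__all__ = [
    "SegmentationParams",
    "Run",
    "Pause",
    "Reversal",
    "RunTable",
    "segment_runs",
    "classify_track",
    "population_stats",
    "PopulationSummary",
    "per_rnp_correlations",
    "CorrelationResult",
    "dwell_time_on_mt",
    "downsample",
]

MINUS = "minus"
PLUS = "plus"


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the thresholded run segmentation.

    run_cutoff
        Displacement threshold in nm (default 22, ~2x tracking accuracy).
    pause_min_frames
        Minimum number of sub-cutoff frames that constitutes a pause.
    pixel_size
        Camera pixel size in nm; a track whose total positional range does
        not exceed one pixel is classified stationary.
    """

    run_cutoff: float = 22.0
    pause_min_frames: int = 1
    pixel_size: float = 105.0

    def __post_init__(self) -> None:
        if self.run_cutoff <= 0:
            raise ValueError("run_cutoff must be positive")
        if self.pause_min_frames < 1:
            raise ValueError("pause_min_frames must be >= 1")


@dataclass
class Run:
    """One bout of uninterrupted above-cutoff motion in a single direction."""

    direction: str  # "minus" or "plus"
    length: float  # nm, sum of |d| over the block (positive)
    duration: float  # s
    velocity: float  # nm/s, length / duration
    termination: str  # pause | reversal | detach | end_of_acquisition | mt_end
    start: int  # first displacement index of the block
    stop: int  # one past the last displacement index


@dataclass
class Pause:
    start: int  # first displacement index
    n_frames: int
    duration: float  # s


@dataclass
class Reversal:
    index: int  # boundary between displacements d[index] and d[index+1]
    position: float  # on-axis position s[index + 1] (nm)


@dataclass
class RunTable:
    """Segmentation result for one track."""

    track_id: str
    runs: list[Run]
    pauses: list[Pause]
    reversals: list[Reversal]
    n_displacements: int
    frame_interval: float
    position_range: float
    classification: str | None = None

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def runs_in(self, direction: str) -> list[Run]:
        return [r for r in self.runs if r.direction == direction]


def segment_runs(
    track: OnAxisTrack,
    params: SegmentationParams = SegmentationParams(),
    *,
    acquisition_n_frames: int | None = None,
    axis_length: float | None = None,
    end_threshold: float = 210.0,
) -> RunTable:
    """Segment an on-axis track into runs, pauses and reversal events.

    Every displacement frame belongs to exactly one run or pause.  A run's
    termination is ``pause`` or ``reversal`` if followed by the respective
    event, ``detach`` if the track ends before ``acquisition_n_frames``,
    ``end_of_acquisition`` if it is curtailed by the end of imaging, and
    ``mt_end`` when ``axis_length`` is supplied and the run terminates
    within ``end_threshold`` nm of either microtubule end.
    """
    d = track.displacements
    cutoff = params.run_cutoff
    label = np.where(np.abs(d) > cutoff, np.sign(d), 0.0).astype(np.int8)

    # group boundaries: change points of the label sequence
    change = np.flatnonzero(np.diff(label)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [label.size]])

    dt = track.frame_interval
    last_frame_is_acq_end = (
        acquisition_n_frames is None or int(track.frames[-1]) >= acquisition_n_frames - 1
    )

    runs: list[Run] = []
    pauses: list[Pause] = []
    for a, b in zip(starts, stops):
        lab = label[a]
        if lab == 0:
            pauses.append(Pause(start=int(a), n_frames=int(b - a), duration=float((b - a) * dt)))
            continue
        length = float(np.sum(np.abs(d[a:b])))
        duration = float((b - a) * dt)
        if b == label.size:
            term = "end_of_acquisition" if last_frame_is_acq_end else "detach"
        elif label[b] == 0:
            term = "pause"
        else:
            term = "reversal"
        if axis_length is not None and term in ("pause", "reversal", "end_of_acquisition"):
            end_pos = track.s[b]
            if end_pos <= end_threshold or end_pos >= axis_length - end_threshold:
                term = "mt_end"
        runs.append(
            Run(
                direction=MINUS if lab < 0 else PLUS,
                length=length,
                duration=duration,
                velocity=length / duration,
                termination=term,
                start=int(a),
                stop=int(b),
            )
        )

    rev_idx = np.flatnonzero((label[:-1] != 0) & (label[1:] == -label[:-1]))
    reversals = [Reversal(index=int(i), position=float(track.s[i + 1])) for i in rev_idx]

    return RunTable(
        track_id=track.track_id,
        runs=runs,
        pauses=pauses,
        reversals=reversals,
        n_displacements=int(d.size),
        frame_interval=dt,
        position_range=track.position_range,
    )


def classify_track(table: RunTable, params: SegmentationParams = SegmentationParams()) -> str:
    """Classify a segmented track as stationary, unidirectional or bidirectional.

    * ``stationary``: total positional range within one pixel;
    * ``unidirectional_minus``: at least one minus-end run and no plus-end
      runs (the processive, transport-driven class);
    * ``unidirectional_plus``: the mirror-image class, reported separately
      because plus-end-only particles are not expected in this assay;
    * ``bidirectional``: runs in both directions, or a motile track with no
      above-cutoff run at all (slow diffusive wander).

    The label is stored on the table and returned.
    """
    if table.position_range <= params.pixel_size:
        label = "stationary"
    else:
        has_minus = any(r.direction == MINUS for r in table.runs)
        has_plus = any(r.direction == PLUS for r in table.runs)
        if has_minus and not has_plus:
            label = "unidirectional_minus"
        elif has_plus and not has_minus:
            label = "unidirectional_plus"
        else:
            label = "bidirectional"
    table.classification = label
    return label


@dataclass
class PopulationSummary:
    """Per-chamber unidirectional fractions and run-level statistics."""

    per_chamber: pd.DataFrame  # chamber, n_motile, n_unidirectional_minus, fraction
    fraction_mean: float  # mean over chambers of the unidirectional-minus fraction
    fraction_sem: float  # SEM over chambers
    run_stats: pd.DataFrame  # per classification x direction mean run length/velocity


def population_stats(
    tables: list[RunTable],
    chamber_ids: list | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> PopulationSummary:
    """Population statistics over classified tracks grouped by imaging chamber.

    The headline statistic is the per-chamber fraction of motile
    (non-stationary) tracks that are exclusively unidirectional-minus,
    summarized as mean +/- SEM *over chambers* (not over particles).
    Chambers without motile tracks are excluded with a warning.
    """
    if chamber_ids is None:
        chamber_ids = [0] * len(tables)
    if len(chamber_ids) != len(tables):
        raise ValueError("chamber_ids must match tables")
    for t in tables:
        if t.classification is None:
            classify_track(t, params)

    rows = []
    for chamber in sorted(set(chamber_ids), key=str):
        labels = [t.classification for t, c in zip(tables, chamber_ids) if c == chamber]
        motile = [lab for lab in labels if lab != "stationary"]
        if not motile:
            warnings.warn(f"chamber {chamber!r} has no motile tracks; excluded")
            continue
        n_uni = sum(lab == "unidirectional_minus" for lab in motile)
        rows.append(
            {
                "chamber": chamber,
                "n_tracks": len(labels),
                "n_motile": len(motile),
                "n_unidirectional_minus": n_uni,
                "fraction_unidirectional": n_uni / len(motile),
            }
        )
    per_chamber = pd.DataFrame(rows)
    if per_chamber.empty:
        raise ValueError("no chamber with motile tracks")
    fracs = per_chamber["fraction_unidirectional"].to_numpy()
    mean = float(np.mean(fracs))
    sem = float(np.std(fracs, ddof=1) / np.sqrt(fracs.size)) if fracs.size > 1 else 0.0

    run_rows = []
    for t in tables:
        for r in t.runs:
            run_rows.append(
                {
                    "classification": t.classification,
                    "direction": r.direction,
                    "length_nm": r.length,
                    "velocity_nm_s": r.velocity,
                    "duration_s": r.duration,
                }
            )
    if run_rows:
        run_stats = (
            pd.DataFrame(run_rows)
            .groupby(["classification", "direction"])
            .agg(
                mean_length_nm=("length_nm", "mean"),
                mean_velocity_nm_s=("velocity_nm_s", "mean"),
                n_runs=("length_nm", "size"),
            )
            .reset_index()
        )
    else:
        run_stats = pd.DataFrame(
            columns=["classification", "direction", "mean_length_nm", "mean_velocity_nm_s", "n_runs"]
        )
    return PopulationSummary(per_chamber, mean, sem, run_stats)


@dataclass
class CorrelationResult:
    """Paired per-particle means with a linear fit (slope, R^2, 95% CI)."""

    per_rnp: pd.DataFrame  # track_id, mean_minus, mean_plus
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]  # 95% confidence interval on the slope
    n: int


def per_rnp_correlations(
    tables: list[RunTable],
    min_runs: int = 20,
    metric: str = "length",
) -> CorrelationResult:
    """Correlate per-particle mean minus- vs plus-end run length or velocity.

    Only bidirectional particles with at least ``min_runs`` runs in total
    enter the analysis, mirroring the ``>= 20 runs`` inclusion rule used
    when relating the two directions of bidirectional transport.  An OLS
    fit of the minus-end means on the plus-end means is returned; a slope
    near 1 indicates no directional bias.
    """
    if metric not in ("length", "velocity"):
        raise ValueError("metric must be 'length' or 'velocity'")
    attr = "length" if metric == "length" else "velocity"
    rows = []
    for t in tables:
        if t.classification != "bidirectional" or t.n_runs < min_runs:
            continue
        minus = [getattr(r, attr) for r in t.runs_in(MINUS)]
        plus = [getattr(r, attr) for r in t.runs_in(PLUS)]
        if not minus or not plus:
            continue
        rows.append({"track_id": t.track_id, "mean_minus": np.mean(minus), "mean_plus": np.mean(plus)})
    df = pd.DataFrame(rows)
    if len(df) < 3:
        raise ValueError(f"only {len(df)} qualifying particles; need >= 3 for a fit")

    import statsmodels.api as sm

    X = sm.add_constant(df["mean_plus"].to_numpy())
    fit = sm.OLS(df["mean_minus"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    return CorrelationResult(
        per_rnp=df,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n=len(df),
    )


def dwell_time_on_mt(
    track: OnAxisTrack, acquisition_n_frames: int | None = None
) -> tuple[float, bool]:
    """Dwell time of a particle on a microtubule, with censoring flag.

    Returns the duration from the first to the last frame of microtubule
    association and ``censored=True`` when the track runs to the end of
    acquisition (the true dwell is then only a lower bound and must be
    excluded from uncensored means).
    """
    dwell = track.duration
    censored = acquisition_n_frames is None or int(track.frames[-1]) >= acquisition_n_frames - 1
    return dwell, censored


def downsample(track: OnAxisTrack, factor: int) -> OnAxisTrack:
    """Temporally downsample an on-axis track by an integer factor.

    Keeps every ``factor``-th frame and scales the frame interval, which
    emulates imaging the same particle with a slower camera.  Useful for
    studying frame-rate artifacts: measured run lengths of diffusive
    particles grow and measured velocities fall at slower frame rates.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return OnAxisTrack(
        track_id=track.track_id,
        mt_id=track.mt_id,
        s=track.s[::factor].copy(),
        frame_interval=track.frame_interval * factor,
        frames=track.frames[::factor] // factor,
    )
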