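"""Synthetic motility, obstacle and photobleaching data.

Generates particle trajectories, populations, obstacle layouts and
stepwise-bleaching fluorescence traces with the statistical structure the
analysis pipeline assumes, so every downstream stage can be exercised and
validated against known ground truth:

* diffusive on-axis motion: 1D Brownian motion along the microtubule axis
  (Gaussian increments of variance ``2 D dt``), giving a linear MSD;
* processive motion: constant-velocity drift (minus-end-directed transport
  is negative), giving a quadratic MSD; the default preset is
  -1200 nm/s, the scale of dynein-driven RNP transport;
* mixed populations with a stated processive fraction;
* i.i.d. Gaussian localization noise per coordinate per frame, calibrated
  so immobile spots reproduce an 11.3 nm frame-to-frame displacement SD;
* static obstacles that block (and thereby reverse) approaching particles
  with a configurable probability;
* end dwells with exponential pause times before detachment;
* stepwise-decaying fluorescence traces from binomially GFP-labeled
  subunits, each labeled fluorophore bleaching at an exponential time.

Determinism: identical seed + config give bit-identical output.  A master
seed expands into per-track substreams, so generating more tracks never
perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encounters import ObstacleMap
from .geometry import MicrotubuleAxis, Trajectory

__all__ = [
    "SimConfig",
    "MotionModel",
    "GroundTruth",
    "FPS_FAST",
    "FPS_SLOW",
    "simulate_track",
    "simulate_population",
    "simulate_immobile_spots",
    "simulate_bleach_trace",
    "simulate_bleach_ensemble",
    "simulate_obstacle_layout",
    "simulate_end_dwell_tracks",
    "default_axis",
]

FPS_FAST = 15.0  # fast-acquisition preset (66 ms/frame)
FPS_SLOW = 4.2  # slow-acquisition preset (236 ms/frame)


@dataclass(frozen=True)
class SimConfig:
    """Imaging/simulation configuration.

    frame_rate
        Frames per second; 15 and 4.2 are the standard acquisition presets.
    n_frames
        Number of frames per track (>= 2).
    pixel_size
        Camera pixel size in nm (105 nm).
    loc_noise_sd
        Gaussian localization noise SD per coordinate per frame, nm.
    seed
        Master seed; identical seed + config gives bit-identical output.
    mt_length
        Microtubule length in nm (default 15 um).
    """

    frame_rate: float = FPS_FAST
    n_frames: int = 300
    pixel_size: float = 105.0
    loc_noise_sd: float = 8.0
    seed: int = 0
    mt_length: float = 15000.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be >= 0")
        if self.mt_length <= 0:
            raise ValueError("mt_length must be positive")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class MotionModel:
    """Generative motion model for one particle.

    mode
        "diffusive", "processive", "stationary" or "switching".
    diffusion_coeff
        D in nm^2/s (diffusive and the diffusive state of "switching").
    velocity
        Signed drift in nm/s; minus-end-directed is negative (processive).
    processive_fraction
        Probability that a population track is processive (population mixes).
    switch_rates
        (rate_to_processive, rate_to_diffusive) in 1/s for "switching".
    """

    mode: str = "diffusive"
    diffusion_coeff: float = 0.0
    velocity: float = 0.0
    processive_fraction: float | None = None
    switch_rates: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("diffusive", "processive", "stationary", "switching"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.processive_fraction is not None and not 0 <= self.processive_fraction <= 1:
            raise ValueError("processive_fraction must lie in [0, 1]")
        if self.mode == "switching" and self.switch_rates is None:
            raise ValueError("switching mode requires switch_rates")


@dataclass
class GroundTruth:
    """Generative truth carried alongside every simulated object."""

    mode: str | None = None
    velocity: float | None = None
    diffusion_coeff: float | None = None
    start_s: float | None = None
    obstacle_outcomes: list[tuple[int, int, str]] = field(default_factory=list)
    # (obstacle index, frame of first contact, "blocked" | "passed")
    end_dwell_s: float | None = None
    end_dwell_censored: bool | None = None
    true_copies: int | None = None
    n_labeled: int | None = None
    bleach_frames: list[int] = field(default_factory=list)


def default_axis(config: SimConfig, mt_id: str = "mt0") -> MicrotubuleAxis:
    """Horizontal axis from (0, 0) (minus end) to (mt_length, 0) (plus end)."""
    return MicrotubuleAxis(mt_id=mt_id, minus_end=(0.0, 0.0), plus_end=(config.mt_length, 0.0))


def _embed(
    s: np.ndarray,
    axis: MicrotubuleAxis,
    config: SimConfig,
    rng: np.random.Generator,
    track_id: str,
) -> Trajectory:
    """Embed on-axis positions in 2D along the axis vector plus noise."""
    pos = np.asarray(axis.minus_end, float) + s[:, None] * axis.unit
    if config.loc_noise_sd > 0:
        pos = pos + rng.normal(0.0, config.loc_noise_sd, size=pos.shape)
    return Trajectory(
        track_id=track_id,
        frames=np.arange(s.size),
        x=pos[:, 0],
        y=pos[:, 1],
        frame_interval=config.frame_interval,
    )


def simulate_track(
    model: MotionModel,
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    axis: MicrotubuleAxis | None = None,
    start_s: float | None = None,
    obstacles: ObstacleMap | None = None,
    block_prob: float = 0.0,
    end_behavior: str = "none",
    track_id: str = "track0",
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one particle trajectory on a microtubule axis.

    The on-axis position evolves per ``model``; the 2D trajectory is the
    on-axis path embedded along the axis vector with i.i.d. Gaussian
    localization noise added per coordinate per frame.

    Parameters
    ----------
    obstacles, block_prob
        If an obstacle map is given, each approach decides with probability
        ``block_prob`` that the punctum blocks: while blocked, crossing
        attempts are reflected at the punctum edge (and the drift sign
        flips for processive motion), producing a reversal.  The decision
        is redrawn each time the particle leaves and re-approaches.
    end_behavior
        "none" (motion unconstrained by the annotated ends) or "reflect"
        (positions reflected at s = 0 and s = mt_length, drift flipped).
    start_s
        Initial on-axis position; defaults to the middle of the axis.

    Returns the 2D trajectory and the ground truth (mode, generative
    parameters, per-obstacle block/pass decisions).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if axis is None:
        axis = default_axis(config)
    if end_behavior not in ("none", "reflect"):
        raise ValueError("end_behavior must be 'none' or 'reflect'")
    dt = config.frame_interval
    n = config.n_frames
    s0 = config.mt_length / 2.0 if start_s is None else float(start_s)

    gt = GroundTruth(
        mode=model.mode,
        velocity=model.velocity,
        diffusion_coeff=model.diffusion_coeff,
        start_s=s0,
    )

    simple = obstacles is None and end_behavior == "none" and model.mode != "switching"
    if simple:
        if model.mode == "stationary":
            s = np.full(n, s0)
        elif model.mode == "processive":
            s = s0 + model.velocity * dt * np.arange(n)
        else:  # diffusive
            steps = rng.normal(0.0, np.sqrt(2.0 * model.diffusion_coeff * dt), size=n - 1)
            s = s0 + np.concatenate([[0.0], np.cumsum(steps)])
        return _embed(s, axis, config, rng, track_id), gt

    # stepwise simulation with obstacle/end interactions and mode switching
    zones = obstacles.static_intervals if obstacles is not None else []
    engaged: dict[int, bool] = {}  # punctum index -> blocked decision while engaged
    esc = config.pixel_size  # disengage once this far outside the punctum
    state = model.mode if model.mode != "switching" else "diffusive"
    vel = model.velocity
    sigma = np.sqrt(2.0 * model.diffusion_coeff * dt)
    s = np.empty(n)
    s[0] = s0
    for i in range(1, n):
        if model.mode == "switching":
            to_proc, to_diff = model.switch_rates
            if state == "diffusive" and rng.random() < 1.0 - np.exp(-to_proc * dt):
                state = "processive"
            elif state == "processive" and rng.random() < 1.0 - np.exp(-to_diff * dt):
                state = "diffusive"
        prev = s[i - 1]
        if state == "stationary":
            step = 0.0
        elif state == "processive":
            step = vel * dt
        else:
            step = rng.normal(0.0, sigma)
        new = prev + step
        for zi, (a, b) in enumerate(zones):
            entering_left = prev < a <= new
            entering_right = prev > b >= new
            if zi in engaged and not (a - esc <= prev <= b + esc):
                del engaged[zi]  # left the vicinity; next approach redecides
            if entering_left or entering_right:
                if zi not in engaged:
                    blocked = rng.random() < block_prob
                    engaged[zi] = blocked
                    gt.obstacle_outcomes.append((zi, i, "blocked" if blocked else "passed"))
                if engaged[zi]:
                    edge = a if entering_left else b
                    new = 2.0 * edge - new
                    if state == "processive":
                        vel = -vel
        if end_behavior == "reflect":
            if new < 0.0:
                new = -new
                vel = -vel
            elif new > config.mt_length:
                new = 2.0 * config.mt_length - new
                vel = -vel
        s[i] = new
    return _embed(s, axis, config, rng, track_id), gt


def _substreams(config: SimConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(ss) for ss in np.random.SeedSequence(config.seed).spawn(n)]


def simulate_population(
    n_tracks: int,
    config: SimConfig,
    processive_fraction: float,
    *,
    processive: MotionModel | None = None,
    diffusive: MotionModel | None = None,
    **track_kwargs,
) -> list[tuple[Trajectory, GroundTruth]]:
    """Simulate a mixed population of processive and diffusive particles.

    Each track is independently processive with probability
    ``processive_fraction`` (default preset: -1200 nm/s minus-end
    transport), otherwise diffusive (default D = 5000 nm^2/s).  Ground
    truth records each track's mode, so classifier recovery of the
    processive fraction can be scored.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if not 0 <= processive_fraction <= 1:
        raise ValueError("processive_fraction must lie in [0, 1]")
    if processive is None:
        processive = MotionModel(mode="processive", velocity=-1200.0)
    if diffusive is None:
        diffusive = MotionModel(mode="diffusive", diffusion_coeff=5000.0)
    out = []
    for i, rng in enumerate(_substreams(config, n_tracks)):
        model = processive if rng.random() < processive_fraction else diffusive
        traj, gt = simulate_track(
            model, config, rng=rng, track_id=f"track{i}", **track_kwargs
        )
        out.append((traj, gt))
    return out


def simulate_immobile_spots(config: SimConfig, n_spots: int) -> list[Trajectory]:
    """Simulate immobile particles: pure localization noise around fixed points.

    With per-coordinate noise SD sigma, the on-axis frame-to-frame
    displacement SD is sigma * sqrt(2); choosing sigma = 11.3 / sqrt(2) nm
    therefore reproduces an 11.3 nm tracking accuracy.  Used to calibrate
    ``measure_tracking_accuracy`` and the derived 22 nm run cutoff.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    model = MotionModel(mode="stationary")
    return [
        simulate_track(model, config, rng=rng, track_id=f"spot{i}")[0]
        for i, rng in enumerate(_substreams(config, n_spots))
    ]


def simulate_bleach_trace(
    true_copies: int,
    label_prob: float,
    step_amplitude: float,
    noise_sd: float,
    bleach_rate: float,
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    background: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a stepwise photobleaching fluorescence trace.

    The number of labeled subunits is Binomial(true_copies, label_prob);
    each labeled fluorophore bleaches at an i.i.d. exponential time with
    rate ``bleach_rate`` (1/s).  Intensity per frame is
    ``step_amplitude x survivors + background + Gaussian noise``; the
    trace decays to baseline once every fluorophore has bleached.
    """
    if not 0 <= label_prob <= 1:
        raise ValueError("label_prob must lie in [0, 1]")
    if step_amplitude <= 0:
        raise ValueError("step_amplitude must be positive")
    if bleach_rate <= 0:
        raise ValueError("bleach_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_frames
    dt = config.frame_interval
    n_labeled = int(rng.binomial(true_copies, label_prob)) if true_copies > 0 else 0
    times = rng.exponential(1.0 / bleach_rate, size=n_labeled)
    bleach_frames = np.minimum(np.ceil(times / dt).astype(int), n)
    frames = np.arange(n)
    survivors = (bleach_frames[None, :] > frames[:, None]).sum(axis=1)
    intensity = step_amplitude * survivors + background
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=n)
    gt = GroundTruth(
        true_copies=true_copies,
        n_labeled=n_labeled,
        bleach_frames=sorted(int(f) for f in bleach_frames),
    )
    return intensity.astype(float), gt


def simulate_bleach_ensemble(
    n_traces: int,
    mean_copies: float,
    label_prob: float,
    config: SimConfig,
    *,
    step_amplitude: float = 1000.0,
    noise_sd: float = 200.0,
    bleach_rate: float | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Simulate an ensemble of bleach traces with a non-integer mean copy number.

    A fractional mean (e.g. 4.36) is realized by mixing the two flanking
    integer copy numbers (4 and 5) in the proportion that yields the
    requested mean; labeled counts are then binomially thinned with
    ``label_prob``.  The default bleach rate gives a mean bleach time of
    one fifth of the acquisition, so steps are well separated yet traces
    reach baseline.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    lo = int(np.floor(mean_copies))
    frac_hi = mean_copies - lo
    if bleach_rate is None:
        bleach_rate = 5.0 / (config.n_frames * config.frame_interval)
    out = []
    for i, rng in enumerate(_substreams(config, n_traces)):
        copies = lo + (1 if rng.random() < frac_hi else 0)
        trace, gt = simulate_bleach_trace(
            copies, label_prob, step_amplitude, noise_sd, bleach_rate, config, rng=rng
        )
        out.append((trace, gt))
    return out


def simulate_obstacle_layout(
    mt_length: float,
    density: float,
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    mt_id: str = "mt0",
) -> ObstacleMap:
    """Place static obstacle puncta uniformly at random along a microtubule.

    The punctum count is Poisson with mean ``density x length`` (density in
    puncta per um, length in nm); each punctum occupies the single
    pixel-width (105 nm by default) footprint containing its center.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = rng.poisson(density * mt_length / 1000.0)
    centers = np.sort(rng.uniform(0.0, mt_length, size=n))
    px = config.pixel_size
    intervals = []
    seen = set()
    for c in centers:
        p = int(c // px)
        if p in seen:  # two centers in one pixel collapse to one punctum
            continue
        seen.add(p)
        intervals.append((p * px, (p + 1) * px))
    return ObstacleMap(mt_id=mt_id, intervals=intervals)


def simulate_end_dwell_tracks(
    n_tracks: int,
    dwell_mean_s: float,
    config: SimConfig,
    *,
    velocity: float = -1200.0,
    start_s: float | None = None,
    rnp_mode: str = "processive",
) -> list[tuple[Trajectory, GroundTruth]]:
    """Simulate particles that run to the minus end, pause, then detach.

    Each particle approaches the minus end at ``velocity`` (nm/s,
    negative), holds at ``s = 0`` for an exponentially distributed dwell
    with mean ``dwell_mean_s``, and then detaches (the track ends).
    Dwells that would outlast the acquisition are truncated and flagged
    censored in the ground truth, mirroring pauses that end abruptly with
    the completion of imaging.
    """
    if dwell_mean_s <= 0:
        raise ValueError("dwell_mean_s must be positive")
    if velocity >= 0:
        raise ValueError("velocity must be negative (minus-end-directed approach)")
    dt = config.frame_interval
    n = config.n_frames
    axis = default_axis(config)
    if start_s is None:
        start_s = min(config.mt_length, abs(velocity) * dt * 10)  # arrive in ~10 frames
    out = []
    for i, rng in enumerate(_substreams(config, n_tracks)):
        arrival = int(np.ceil(start_s / (abs(velocity) * dt)))
        dwell = rng.exponential(dwell_mean_s)
        n_dwell = max(1, int(np.ceil(dwell / dt)))
        censored = arrival + n_dwell >= n
        n_total = n if censored else arrival + n_dwell + 1
        approach = np.maximum(start_s + velocity * dt * np.arange(arrival + 1), 0.0)
        s = np.concatenate([approach, np.zeros(max(0, n_total - arrival - 1))])[:n_total]
        traj = _embed(s, axis, config, rng, f"track{i}")
        gt = GroundTruth(
            mode=rnp_mode,
            velocity=velocity,
            start_s=start_s,
            end_dwell_s=float(dwell),
            end_dwell_censored=censored,
        )
        out.append((traj, gt))
    return out
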