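"""Run/pause/reversal segmentation, classification and population statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnptrack import (
    MotionModel,
    Run,
    RunTable,
    SegmentationParams,
    SimConfig,
    classify_track,
    default_axis,
    downsample,
    dwell_time_on_mt,
    per_rnp_correlations,
    population_stats,
    project_onto_axis,
    segment_runs,
    simulate_track,
)

from conftest import track_from_displacements


def reference_segment(d, cutoff=22.0):
    """Brute-force oracle: a literal loop over the segmentation rules.

    Returns (runs, pauses, reversals) where runs are
    (start, stop, sign, summed length), pauses are (start, n_frames) and
    reversals are boundary indices i with |sign(d_i) - sign(d_{i+1})| = 2
    and both displacements above cutoff.
    """
    runs, pauses, reversals = [], [], []
    n = len(d)
    i = 0
    while i < n:
        if abs(d[i]) <= cutoff:
            j = i
            while j < n and abs(d[j]) <= cutoff:
                j += 1
            pauses.append((i, j - i))
            i = j
        else:
            sgn = 1 if d[i] > 0 else -1
            j = i
            while j < n and abs(d[j]) > cutoff and (d[j] > 0) == (sgn > 0):
                j += 1
            runs.append((i, j, sgn, sum(abs(d[k]) for k in range(i, j))))
            i = j
    for i in range(n - 1):
        if abs(d[i]) > cutoff and abs(d[i + 1]) > cutoff:
            sgn = lambda v: 1 if v > 0 else -1
            if abs(sgn(d[i]) - sgn(d[i + 1])) == 2:
                reversals.append(i)
    return runs, pauses, reversals


def assert_matches_reference(d, cutoff=22.0):
    table = segment_runs(track_from_displacements(d), SegmentationParams(run_cutoff=cutoff))
    ref_runs, ref_pauses, ref_revs = reference_segment(d, cutoff)
    assert [(r.start, r.stop) for r in table.runs] == [(a, b) for a, b, _, _ in ref_runs]
    assert [r.direction for r in table.runs] == [
        "plus" if sgn > 0 else "minus" for _, _, sgn, _ in ref_runs
    ]
    for run, (_, _, _, length) in zip(table.runs, ref_runs):
        assert run.length == pytest.approx(length)
    assert [(p.start, p.n_frames) for p in table.pauses] == ref_pauses
    assert [r.index for r in table.reversals] == ref_revs


class TestSegmentRuns:
    def test_run_pause_run(self):
        """d = [+30, +30, -10, +30]: run(+, 60), 1-frame pause, run(+, 30)."""
        table = segment_runs(track_from_displacements([30, 30, -10, 30]))
        assert [(r.direction, r.length) for r in table.runs] == [("plus", 60.0), ("plus", 30.0)]
        assert [(p.start, p.n_frames) for p in table.pauses] == [(2, 1)]
        assert table.reversals == []
        assert table.runs[0].termination == "pause"

    def test_sign_flip_above_cutoff_is_a_reversal(self):
        """d = [+30, -30]: two 30-nm runs joined by one reversal."""
        table = segment_runs(track_from_displacements([30, -30]))
        assert [(r.direction, r.length) for r in table.runs] == [("plus", 30.0), ("minus", 30.0)]
        assert len(table.reversals) == 1 and table.reversals[0].index == 0
        assert table.runs[0].termination == "reversal"

    def test_all_subcutoff_is_one_pause(self):
        table = segment_runs(track_from_displacements([10, -15, 5, 22, -22]))
        assert table.runs == []
        assert len(table.pauses) == 1 and table.pauses[0].n_frames == 5

    def test_velocity_equals_length_over_duration(self):
        table = segment_runs(track_from_displacements([30, 40, 50]))
        (run,) = table.runs
        assert run.velocity == pytest.approx(run.length / run.duration)

    def test_detach_vs_end_of_acquisition(self):
        t = track_from_displacements([30, 30])
        assert segment_runs(t).runs[0].termination == "end_of_acquisition"
        assert (
            segment_runs(t, acquisition_n_frames=100).runs[0].termination == "detach"
        )

    def test_mt_end_termination(self):
        t = track_from_displacements([-30, -30], start=160.0)  # ends at 100 nm from minus end
        table = segment_runs(t, axis_length=15000.0, end_threshold=210.0)
        assert table.runs[0].termination == "mt_end"

    @given(
        st.lists(
            st.floats(min_value=-120, max_value=120, allow_nan=False), min_size=2, max_size=60
        )
    )
    def test_matches_brute_force_oracle(self, d):
        assert_matches_reference(d)

    @given(st.integers(0, 2**31 - 1))
    def test_partition_property(self, seed):
        """Every displacement frame is in exactly one run or pause."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 40, size=rng.integers(2, 80))
        table = segment_runs(track_from_displacements(d))
        covered = sum(r.stop - r.start for r in table.runs) + sum(
            p.n_frames for p in table.pauses
        )
        assert covered == table.n_displacements

    @given(st.integers(0, 2**31 - 1))
    def test_raising_cutoff_never_adds_runs(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 40, size=50)
        n22 = len(segment_runs(track_from_displacements(d), SegmentationParams(run_cutoff=22)).runs)
        n40 = len(segment_runs(track_from_displacements(d), SegmentationParams(run_cutoff=40)).runs)
        assert n40 <= n22


class TestClassification:
    def test_minus_only_is_unidirectional(self):
        table = segment_runs(track_from_displacements([-60, -60, -60]))
        assert classify_track(table) == "unidirectional_minus"

    def test_subpixel_range_is_stationary(self):
        """80 nm of total range is within one 105-nm pixel."""
        table = segment_runs(track_from_displacements([40, 40, -40, -40]))
        assert table.position_range == pytest.approx(80.0)
        assert classify_track(table) == "stationary"

    def test_both_directions_is_bidirectional(self):
        table = segment_runs(track_from_displacements([60, 60, -60, 60, -60]))
        assert classify_track(table) == "bidirectional"

    def test_plus_only_reported_separately(self):
        table = segment_runs(track_from_displacements([60, 60, 30]))
        assert classify_track(table) == "unidirectional_plus"


class TestPopulationStats:
    def test_all_bidirectional_gives_zero_fraction(self):
        tables = [
            segment_runs(track_from_displacements([120, -120, 120, -120])) for _ in range(6)
        ]
        summary = population_stats(tables, chamber_ids=[0, 0, 0, 1, 1, 1])
        assert summary.fraction_mean == 0.0
        assert summary.fraction_sem == 0.0

    def test_chamber_without_motile_tracks_excluded(self):
        motile = segment_runs(track_from_displacements([-60, -60, -60, -60]))
        still = segment_runs(track_from_displacements([10, -10, 10]))
        with pytest.warns(UserWarning, match="no motile"):
            summary = population_stats([motile, still], chamber_ids=[0, 1])
        assert len(summary.per_chamber) == 1
        assert summary.fraction_mean == 1.0


def _mirror_table(track_id, lengths):
    """Bidirectional table whose minus and plus run statistics are identical."""
    runs = []
    for ln in lengths:
        for direction in ("minus", "plus"):
            runs.append(
                Run(direction=direction, length=ln, duration=1.0, velocity=ln,
                    termination="reversal", start=0, stop=1)
            )
    return RunTable(
        track_id=track_id, runs=runs, pauses=[], reversals=[],
        n_displacements=2 * len(lengths), frame_interval=1.0,
        position_range=1000.0, classification="bidirectional",
    )


class TestCorrelations:
    def test_mirrored_runs_fit_identity_line(self):
        """Per-particle mean minus vs plus run lengths on y = x give R^2 = 1."""
        rng = np.random.default_rng(0)
        tables = [_mirror_table(f"t{i}", rng.uniform(50, 400, size=12)) for i in range(8)]
        res = per_rnp_correlations(tables, min_runs=20)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_pairing_destroys_correlation(self):
        rng = np.random.default_rng(1)
        tables = []
        for i in range(30):
            t = _mirror_table(f"t{i}", rng.uniform(50, 400, size=12))
            # re-scale the plus runs of each particle by an independent factor
            for r in t.runs:
                if r.direction == "plus":
                    r.length = float(rng.uniform(50, 400))
            tables.append(t)
        res = per_rnp_correlations(tables, min_runs=20)
        assert res.r_squared < 0.3

    def test_refuses_fit_with_fewer_than_three_particles(self):
        tables = [_mirror_table("a", np.full(12, 100.0))]
        with pytest.raises(ValueError, match="need >= 3"):
            per_rnp_correlations(tables, min_runs=20)

    def test_min_runs_filter_applies(self):
        tables = [_mirror_table(f"t{i}", np.full(5, 100.0)) for i in range(5)]  # 10 runs each
        with pytest.raises(ValueError):
            per_rnp_correlations(tables, min_runs=20)


class TestDwellAndDownsampling:
    def test_dwell_time_is_span_times_frame_interval(self):
        t = track_from_displacements(np.full(100, -30.0), frame_interval=1 / 4.2)
        dwell, censored = dwell_time_on_mt(t, acquisition_n_frames=500)
        assert dwell == pytest.approx(100 / 4.2)
        assert not censored

    def test_acquisition_end_dwell_is_censored(self):
        t = track_from_displacements(np.full(99, -30.0), frame_interval=1 / 4.2)
        _, censored = dwell_time_on_mt(t, acquisition_n_frames=100)
        assert censored

    def test_exponential_dwell_recovery(self):
        rng = np.random.default_rng(2)
        true_mean = 30.0
        dt = 1 / 4.2
        dwells = []
        for _ in range(150):
            n = max(2, int(np.ceil(rng.exponential(true_mean) / dt)) + 1)
            t = track_from_displacements(np.zeros(n - 1), frame_interval=dt)
            dwells.append(dwell_time_on_mt(t, acquisition_n_frames=10**6)[0])
        est = np.mean(dwells)
        sem = np.std(dwells, ddof=1) / np.sqrt(len(dwells))
        assert abs(est - true_mean) < 3 * sem + dt  # dt: frame-quantization slack

    def test_slower_sampling_inflates_run_length_and_deflates_velocity(self):
        """Downsampling diffusive tracks from 15 fps mimics a slower camera:
        measured run lengths rise and measured velocities fall."""
        cfg = SimConfig(frame_rate=15.0, n_frames=1200, seed=8)
        axis = default_axis(cfg)
        fast_runs, slow_runs = [], []
        from numpy.random import SeedSequence, default_rng

        for i, ss in enumerate(SeedSequence(8).spawn(20)):
            traj, _ = simulate_track(
                MotionModel(mode="diffusive", diffusion_coeff=5000.0),
                cfg,
                rng=default_rng(ss),
                track_id=f"d{i}",
            )
            t = project_onto_axis(traj, axis)
            fast_runs.extend(segment_runs(t).runs)
            slow_runs.extend(segment_runs(downsample(t, 4)).runs)
        assert np.mean([r.length for r in slow_runs]) > np.mean([r.length for r in fast_runs])
        assert np.mean([r.velocity for r in slow_runs]) < np.mean(
            [r.velocity for r in fast_runs]
        )
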