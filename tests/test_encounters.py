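"""Obstacle and microtubule-end encounter scoring, and the chance null."""

import numpy as np
import pytest
from numpy.random import SeedSequence, default_rng

from rnptrack import (
    MotionModel,
    ObstacleMap,
    SimConfig,
    classify_track,
    compare_outcomes,
    default_axis,
    mean_end_pause,
    outcome_fractions,
    project_onto_axis,
    score_end_encounters,
    score_obstacle_encounters,
    segment_runs,
    simulate_end_dwell_tracks,
    simulate_null_encounters,
    simulate_obstacle_layout,
    simulate_track,
)
from rnptrack.encounters import EncounterRecord

from conftest import track_from_displacements


def _segmented(d, **kw):
    t = track_from_displacements(d, **kw)
    tab = segment_runs(t)
    classify_track(tab)
    return t, tab


def _records(outcomes, approach="minus"):
    return [
        EncounterRecord(track_id=f"t{i}", obstacle_index=0, approach=approach, outcome=o, frame=i)
        for i, o in enumerate(outcomes)
    ]


class TestObstacleScoring:
    def test_traversing_run_scores_pass(self):
        # plus run from 7000 through a punctum at [7350, 7455]
        t, tab = _segmented(np.full(20, 60.0), start=7000.0)
        obstacles = ObstacleMap("mt0", [(7350.0, 7455.0)])
        (rec,) = score_obstacle_encounters(t, tab, obstacles)
        assert rec.outcome == "pass" and rec.approach == "plus"

    def test_blocking_obstacle_scores_reversal(self):
        cfg = SimConfig(frame_rate=15.0, n_frames=200, seed=1)
        obstacles = ObstacleMap("mt0", [(5250.0, 5355.0)])
        traj, gt = simulate_track(
            MotionModel(mode="processive", velocity=-1200.0),
            cfg,
            obstacles=obstacles,
            block_prob=1.0,
            track_id="b0",
        )
        t = project_onto_axis(traj, default_axis(cfg))
        tab = segment_runs(t)
        recs = score_obstacle_encounters(t, tab, obstacles)
        assert recs and recs[0].outcome == "reversal"
        assert gt.obstacle_outcomes[0][2] == "blocked"

    def test_no_obstacles_no_encounters(self):
        t, tab = _segmented([60, -60, 60, -60])
        assert score_obstacle_encounters(t, tab, ObstacleMap("mt0", [])) == []

    def test_whole_microtubule_obstacle(self):
        """With the obstacle covering the whole axis, every run that is not
        the bounce-back of a reversal opens an encounter."""
        rng = np.random.default_rng(3)
        t, tab = _segmented(rng.normal(0, 60, 100))
        obstacles = ObstacleMap("mt0", [(0.0, 15000.0)])
        recs = score_obstacle_encounters(t, tab, obstacles)
        expected = sum(
            1
            for i, r in enumerate(tab.runs)
            if i == 0 or tab.runs[i - 1].direction == r.direction
        )
        assert len(recs) == expected > 0

    def test_overlapping_puncta_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            m = ObstacleMap("mt0", [(100.0, 300.0), (200.0, 400.0)])
        assert m.intervals == [(100.0, 400.0)]

    def test_nonstationary_puncta_excluded_from_scoring(self):
        t, tab = _segmented(np.full(20, 60.0), start=7000.0)
        moving = ObstacleMap("mt0", [(7350.0, 7455.0)], stationary=[False])
        assert score_obstacle_encounters(t, tab, moving) == []

    def test_outcome_fractions_sum_to_one(self):
        recs = _records(["pass", "reversal", "reversal", "pause", "detach"])
        assert outcome_fractions(recs).sum() == pytest.approx(1.0)

    def test_fully_blocking_obstacles_give_all_reversals(self):
        cfg = SimConfig(frame_rate=15.0, n_frames=400, seed=11)
        layout = simulate_obstacle_layout(15000.0, 0.4, SimConfig(seed=99))
        recs = []
        for i, ss in enumerate(SeedSequence(11).spawn(15)):
            traj, _ = simulate_track(
                MotionModel(mode="processive", velocity=-1200.0),
                cfg,
                rng=default_rng(ss),
                obstacles=layout,
                block_prob=1.0,
                end_behavior="reflect",
                track_id=f"p{i}",
            )
            t = project_onto_axis(traj, default_axis(cfg))
            tab = segment_runs(t)
            recs.extend(score_obstacle_encounters(t, tab, layout))
        fr = outcome_fractions(recs)
        assert fr.get("reversal", 0.0) == pytest.approx(1.0)


class TestNullSimulation:
    @staticmethod
    def _free_tracks(seed, n=40):
        cfg = SimConfig(frame_rate=15.0, n_frames=300, seed=seed)
        axis = default_axis(cfg)
        out = []
        for i, ss in enumerate(SeedSequence(seed).spawn(n)):
            traj, _ = simulate_track(
                MotionModel(mode="diffusive", diffusion_coeff=5000.0),
                cfg,
                rng=default_rng(ss),
                track_id=f"f{i}",
            )
            t = project_onto_axis(traj, axis)
            tab = segment_runs(t)
            classify_track(tab)
            out.append((t, tab))
        return out

    def test_zero_obstacles_zero_encounters(self):
        tracks = self._free_tracks(1, n=3)
        assert simulate_null_encounters(tracks, [ObstacleMap("m", [])]) == []

    def test_chance_coincidence_increases_with_density(self):
        tracks = self._free_tracks(2)
        counts = []
        for density in (0.05, 0.4, 1.2):
            layouts = [
                simulate_obstacle_layout(
                    15000.0, density, SimConfig(seed=1), rng=default_rng(500 + i), mt_id=f"l{i}"
                )
                for i in range(8)
            ]
            counts.append(len(simulate_null_encounters(tracks, layouts)))
        assert counts[0] < counts[1] < counts[2]

    def test_empty_layout_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_encounters(self._free_tracks(1, n=2), [])


class TestCompareOutcomes:
    def test_identical_tables_give_p_one(self):
        recs = _records(["reversal"] * 10 + ["pass"] * 30)
        df = compare_outcomes(recs, recs)
        assert np.allclose(df["fisher_p"], 1.0)

    def test_strong_contrast_highly_significant(self):
        obs = _records(["reversal"] * 70 + ["pass"] * 30)
        null = _records(["reversal"] * 10 + ["pass"] * 90)
        df = compare_outcomes(obs, null).set_index("outcome")
        assert df.loc["reversal", "fisher_p"] < 1e-6

    def test_single_encounter_each_no_crash(self):
        df = compare_outcomes(_records(["reversal"]), _records(["pass"]))
        assert ((df["fisher_p"] > 0) & (df["fisher_p"] <= 1)).all()

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            compare_outcomes([], _records(["pass"]))

    def test_direction_stratification(self):
        obs = _records(["reversal"] * 5, "minus") + _records(["pass"] * 5, "plus")
        null = _records(["pass"] * 5, "minus") + _records(["pass"] * 5, "plus")
        df = compare_outcomes(obs, null, stratify_by_approach=True)
        assert set(df["approach"]) == {"minus", "plus"}


class TestEndEncounters:
    def test_reflecting_plus_end_always_reverses(self):
        """A transport-driven particle bouncing off the plus end at the
        end-encounter frame rate (4.2 fps) is always scored as a reversal."""
        cfg = SimConfig(frame_rate=4.2, n_frames=400, seed=5)
        axis = default_axis(cfg)
        outcomes = []
        for i, ss in enumerate(SeedSequence(5).spawn(10)):
            traj, _ = simulate_track(
                MotionModel(mode="processive", velocity=1200.0),
                cfg,
                rng=default_rng(ss),
                start_s=1000.0,
                end_behavior="reflect",
                track_id=f"r{i}",
            )
            t = project_onto_axis(traj, axis)
            tab = segment_runs(t)
            outcomes += [
                e.outcome
                for e in score_end_encounters(
                    t, tab, cfg.mt_length, acquisition_n_frames=cfg.n_frames
                )
                if e.end == "plus"
            ]
        assert outcomes and all(o == "reversal" for o in outcomes)

    def test_brief_end_contact_then_track_end_is_detach(self):
        cfg = SimConfig(frame_rate=4.2, n_frames=300, seed=6)
        traj, _ = simulate_end_dwell_tracks(1, 0.05, cfg)[0]
        t = project_onto_axis(traj, default_axis(cfg))
        tab = segment_runs(t)
        encs = score_end_encounters(t, tab, cfg.mt_length, acquisition_n_frames=cfg.n_frames)
        assert [e.outcome for e in encs if e.end == "minus"] == ["detach"]

    def test_exponential_dwell_recovery_within_two_sem(self):
        cfg = SimConfig(frame_rate=4.2, n_frames=800, seed=4)
        tracks = simulate_end_dwell_tracks(60, 10.7, cfg)
        encs = []
        for traj, _ in tracks:
            t = project_onto_axis(traj, default_axis(cfg))
            tab = segment_runs(t)
            encs.extend(
                score_end_encounters(t, tab, cfg.mt_length, acquisition_n_frames=cfg.n_frames)
            )
        mean, sem, n = mean_end_pause(encs, "minus")
        assert n >= 50
        assert abs(mean - 10.7) <= 2 * sem + 2 / 4.2  # frame-quantization slack

    def test_censored_pause_excluded_from_uncensored_mean(self):
        cfg = SimConfig(frame_rate=4.2, n_frames=60, seed=7)
        tracks = simulate_end_dwell_tracks(5, 1000.0, cfg)  # all dwells outlast imaging
        encs = []
        for traj, _ in tracks:
            t = project_onto_axis(traj, default_axis(cfg))
            tab = segment_runs(t)
            encs.extend(
                score_end_encounters(t, tab, cfg.mt_length, acquisition_n_frames=cfg.n_frames)
            )
        assert all(e.censored for e in encs if e.outcome == "pause")
        with pytest.raises(ValueError, match="no qualifying pauses"):
            mean_end_pause(encs, "minus")

    def test_track_far_from_ends_yields_no_records(self):
        t, tab = _segmented([60.0, -60.0, 60.0], start=7500.0)
        assert score_end_encounters(t, tab, 15000.0) == []
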