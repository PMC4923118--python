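"""Generators: videos, gaze traces, cohorts, beta volumes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from salcomp.gaze import detect_fixations, gaze_lateralization_index, trial_qc
from salcomp.geometry import ScreenGeometry
from salcomp.pipeline import annotate_trials
from salcomp.synthetic import (
    CohortSpec,
    GazeModelParams,
    frame_counts_for_set,
    generate_beta_volumes,
    generate_cohort,
    generate_gaze_trace,
    generate_scene_layout,
    generate_video,
    horizontal_flip,
    mirror_truth,
)
from salcomp.synthetic.cohort import _corrupt_trace


class TestVideos:
    def test_lat_right_event_stays_right(self):
        _, truth = generate_video("lat", "right", clutter_mean=6.3, seed=1)
        assert len(truth.event_trajectories) == 1
        assert np.all(truth.event_trajectories[0][:, 0] > 0)

    def test_multi_has_one_event_per_hemifield(self):
        _, truth = generate_video("multi", "left", clutter_mean=7.3, seed=2)
        signs = {np.sign(t[:, 0].mean()) for t in truth.event_trajectories}
        assert signs == {-1.0, 1.0}
        assert truth.true_lateralization < 0  # side label consistent

    def test_seed_reproducibility(self):
        a, _ = generate_video("multi", "right", seed=9)
        b, _ = generate_video("multi", "right", seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_pixel_range_and_frame_count(self):
        video, _ = generate_video("lat", "left", seed=3, fps=25, duration_s=1.5)
        assert 0.0 <= video.frames.min() and video.frames.max() <= 1.0
        assert abs(video.n_frames - round(1.5 * 25)) <= 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ScreenGeometry(width_px=-1)
        with pytest.raises(ValueError):
            generate_video("lat", "right", clutter_mean=-2.0)

    def test_stimulus_set_totals_5250_frames(self):
        counts = frame_counts_for_set(140, fps=25.0, duration_s=1.5)
        assert counts.sum() == 5250
        assert set(counts) == {37, 38}

    def test_flip_is_involution_and_swaps_side(self):
        video, _ = generate_video("lat", "right", seed=5, n_frames=4)
        flipped = horizontal_flip(video)
        assert flipped.side == "left" and flipped.flipped
        again = horizontal_flip(flipped)
        assert np.array_equal(again.frames, video.frames)
        assert again.side == "right" and not again.flipped

    def test_mirror_truth_negates_lateralization(self):
        _, truth = generate_video("multi", "right", seed=8)
        mirrored = mirror_truth(truth)
        assert mirrored.true_lateralization == -truth.true_lateralization
        assert mirrored.side == "left"


class TestGazeGenerator:
    def test_lat_gaze_index_near_planted_bias(self):
        """side_bias 0.9 toward a right event -> E[gaze_idx] = +0.8."""
        params = GazeModelParams(blink_prob_per_s=0.0)
        rng = np.random.default_rng(0)
        vals = []
        for k in range(300):
            truth = generate_scene_layout("lat", "right", seed=rng)
            trace = generate_gaze_trace(
                {"condition": "lat", "side": "right", "sal_idx": truth.true_lateralization},
                truth, params, seed=rng,
            )
            vals.append(gaze_lateralization_index(trace).gaze_idx)
        assert np.nanmean(vals) == pytest.approx(0.8, abs=0.05)

    def test_zero_coupling_multi_is_unbiased(self):
        params = GazeModelParams(coupling_gamma=0.0, blink_prob_per_s=0.0)
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(300):
            truth = generate_scene_layout("multi", "right", seed=rng)
            trace = generate_gaze_trace(
                {"condition": "multi", "side": "right", "sal_idx": truth.true_lateralization},
                truth, params, seed=rng,
            )
            vals.append(gaze_lateralization_index(trace).gaze_idx)
        assert abs(np.nanmean(vals)) < 0.06

    def test_huge_dwell_yields_single_fixation(self):
        params = GazeModelParams(
            dwell_mean_s={"lat": 10.0, "multi": 10.0}, blink_prob_per_s=0.0
        )
        truth = generate_scene_layout("lat", "right", seed=2)
        trace = generate_gaze_trace(
            {"condition": "lat", "side": "right", "sal_idx": 0.5}, truth, params, seed=3
        )
        stim = trace.stimulus_slice()
        sub_fixes = [
            f for f in detect_fixations(trace) if f.onset_s >= trace.stimulus_onset_s - 1e-9
        ]
        assert len(sub_fixes) == 1
        assert stim.sum() == 180  # 1.5 s at 120 Hz

    def test_seeded_trace_reproducible(self):
        truth = generate_scene_layout("multi", "left", seed=4)
        trial = {"condition": "multi", "side": "left", "sal_idx": -0.2}
        a = generate_gaze_trace(trial, truth, seed=7)
        b = generate_gaze_trace(trial, truth, seed=7)
        assert np.array_equal(a.x_deg, b.x_deg) and np.array_equal(a.valid, b.valid)

    def test_corruption_modes_fail_qc(self):
        rng = np.random.default_rng(5)
        truth = generate_scene_layout("lat", "right", seed=6)
        trial = {"condition": "lat", "side": "right", "sal_idx": 0.6}
        params = GazeModelParams(blink_prob_per_s=0.0)
        off = _corrupt_trace(generate_gaze_trace(trial, truth, params, seed=8), "off_center", rng)
        assert not trial_qc(off).passed
        blink = _corrupt_trace(generate_gaze_trace(trial, truth, params, seed=9), "blink_loss", rng)
        assert not trial_qc(blink).passed


class TestCohort:
    def test_condition_and_cell_counts(self, small_cohort):
        per_subject = small_cohort.trials.groupby("subject")
        for _, sub in per_subject:
            assert len(sub) == 24
            counts = sub.groupby("condition").size()
            assert counts["lat"] == 12 and counts["multi"] == 12
            runs = sub.groupby("run").size()
            assert set(runs) == {12}

    def test_flip_balanced_across_subjects(self, small_cohort):
        flips = small_cohort.trials.groupby("base_video_id")["flipped"].sum()
        assert set(flips) == {2}  # half of the 4 subjects see each video mirrored

    def test_onsets_increase_and_itis_within_range(self, small_cohort):
        for (_, _), sub in small_cohort.trials.groupby(["subject", "run"]):
            onsets = sub["onset_s"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
            gaps = np.diff(onsets) - 1.5
            assert np.all(gaps >= 3.0 - 1e-9) and np.all(gaps <= 7.4 + 1e-9)

    def test_iti_mean_matches_uniform_midpoint(self):
        rng = np.random.default_rng(0)
        draws = rng.uniform(3.0, 7.4, 10000)
        assert draws.mean() == pytest.approx(5.2, abs=0.05)

    def test_clean_cohort_passes_qc_everywhere(self, small_cohort):
        annotated = annotate_trials(small_cohort.trials, small_cohort.traces)
        assert annotated["qc_pass"].all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_videos=10, n_lat=5, n_multi=5)  # odd cells
        with pytest.raises(ValueError):
            CohortSpec(n_videos=10, n_lat=4, n_multi=4)

    def test_cohort_reproducible(self):
        spec = CohortSpec(n_subjects=2, n_videos=8, n_lat=4, n_multi=4,
                          corrupt_fraction=0.0, n_noncompliant_subjects=0)
        a = generate_cohort(spec, seed=3)
        b = generate_cohort(spec, seed=3)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert np.array_equal(a.traces[0].x_deg, b.traces[0].x_deg)


class TestBetaVolumes:
    def test_structure_24_volumes_in_6_sets(self):
        betas, gm = generate_beta_volumes(2, seed=0)
        assert len(betas) == 2
        for b in betas:
            assert b.data.shape[0] == 24
            sets = b.labels.groupby(["run", "subgroup"]).size()
            assert len(sets) == 6 and set(sets) == {4}
        assert gm.shape == (16, 16, 16)

    def test_null_amplitude_has_no_condition_difference(self):
        betas, _ = generate_beta_volumes(6, effect_amplitude=0.0, seed=1)
        from salcomp.synthetic.volumes import default_informative_region

        region = default_informative_region((16, 16, 16))
        tvals = []
        for b in betas:
            multi = b.data[(b.labels["condition"] == "multi").to_numpy()][:, region]
            lat = b.data[(b.labels["condition"] == "lat").to_numpy()][:, region]
            diff = multi.mean(axis=0) - lat.mean(axis=0)
            tvals.append(diff / (1.0 * np.sqrt(2 / 12)))
        tvals = np.concatenate(tvals)
        assert np.mean(np.abs(tvals) < 3) > 0.95

    def test_large_amplitude_linearly_separable_in_region(self):
        betas, _ = generate_beta_volumes(1, effect_amplitude=8.0, seed=2)
        from salcomp.synthetic.volumes import default_informative_region

        b = betas[0]
        region = default_informative_region((16, 16, 16))
        X = b.data[:, region]
        y = (b.labels["condition"] == "multi").to_numpy()
        from sklearn.svm import SVC

        clf = SVC(kernel="linear", C=1.0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_beta_volumes(1, grid_dims=(12, 12, 12),
                                  informative_region=np.ones((16, 16, 16), bool))
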