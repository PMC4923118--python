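"""Cohort-level simulation: stimulus set, schedules, traces, corruption.

A cohort is a set of subjects who each view the full stimulus set (default
140 videos: 80 lat + 60 multi, equally split left/right) across runs in a
per-subject random order, with uniform inter-trial intervals.  Video
flipping is balanced across subjects: every video is seen mirrored by half
of the cohort (the trial then carries the mirrored side label and negated
salience index, and its ``video_id`` gains an ``F`` suffix so per-video
aggregation stays orientation-consistent).

A configurable fraction of trials is corrupted (off-centre pre-stimulus
position or heavy blink loss) to exercise the quality controls, and a few
designated non-compliant subjects receive a high corruption rate so that
subject-level selection (>= 6 passing trials per condition cell) excludes
them, emulating a 19-subject cohort with 16 usable participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import ScreenGeometry, DEFAULT_GEOMETRY
from ..gaze import GazeTrace
from ..design import build_schedule
from .videos import (
    GroundTruth,
    VideoStimulus,
    frame_counts_for_set,
    generate_scene_layout,
    mirror_truth,
    render_video,
)
from .gaze import GazeModelParams, generate_gaze_trace

__all__ = ["CohortSpec", "CohortData", "generate_cohort"]


@dataclass
class CohortSpec:
    """Study-design constants of a simulated cohort."""

    n_subjects: int = 19
    n_videos: int = 140
    n_lat: int = 80
    n_multi: int = 60
    n_runs: int = 2
    iti_min_s: float = 3.0
    iti_max_s: float = 7.4
    duration_s: float = 1.5
    fps: float = 25.0
    clutter_mean_lat: float = 6.3
    clutter_mean_multi: float = 7.3
    corrupt_fraction: float = 0.10
    n_noncompliant_subjects: int = 3
    noncompliant_corrupt_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.n_lat + self.n_multi != self.n_videos:
            raise ValueError("n_lat + n_multi must equal n_videos")
        if self.n_lat % 2 or self.n_multi % 2:
            raise ValueError("n_lat and n_multi must be even (equal left/right split)")
        if not 0 <= self.corrupt_fraction <= 1:
            raise ValueError("corrupt_fraction must be a probability")
        if self.n_noncompliant_subjects > self.n_subjects:
            raise ValueError("more non-compliant subjects than subjects")


@dataclass
class CohortData:
    """Generated cohort: stimulus metadata, trials, traces, layouts."""

    spec: CohortSpec
    geometry: ScreenGeometry
    videos: pd.DataFrame  # one row per canonical video
    trials: pd.DataFrame  # one row per subject x video presentation
    traces: list  # GazeTrace, aligned with trials rows
    layouts: dict  # video_id -> GroundTruth (canonical orientation)
    video_seeds: dict = field(default_factory=dict)

    def layout_for_trial(self, row) -> GroundTruth:
        base = self.layouts[row["base_video_id"]]
        return mirror_truth(base) if row["flipped"] else base

    def render(self, base_video_id: str, flipped: bool = False) -> VideoStimulus:
        """Render a video's frames on demand (frames are not kept in memory)."""
        truth = self.layouts[base_video_id]
        if flipped:
            truth = mirror_truth(truth)
        return render_video(
            truth, self.geometry, self.spec.fps, self.spec.duration_s, base_video_id
        )


def _corrupt_trace(trace: GazeTrace, mode: str, rng: np.random.Generator) -> GazeTrace:
    if mode == "off_center":
        # planted pre-stimulus offset of 3 degrees: must fail positional QC
        pre = trace.time_s < trace.stimulus_onset_s
        trace.x_deg[pre] = 3.0 + 0.05 * rng.standard_normal(int(pre.sum()))
    elif mode == "blink_loss":
        stim = trace.stimulus_slice()
        idx = np.flatnonzero(stim)
        kill = rng.choice(idx, size=int(0.6 * len(idx)), replace=False)
        trace.valid[kill] = False
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return trace


def generate_cohort(
    spec: CohortSpec | None = None,
    gaze_params: GazeModelParams | None = None,
    geometry: ScreenGeometry | None = None,
    seed: int = 0,
) -> CohortData:
    """Simulate a full cohort (layouts, schedules and gaze traces).

    Video frames are not rendered here (use :meth:`CohortData.render`);
    gaze generation uses each video's planted salience lateralization as
    its ``sal_idx``.  Same seed: identical cohort.
    """
    spec = spec or CohortSpec()
    gaze_params = gaze_params or GazeModelParams()
    geometry = geometry or DEFAULT_GEOMETRY
    root = np.random.SeedSequence(seed)
    ss_videos, ss_flip, ss_sched, ss_trace = root.spawn(4)
    rng_flip = np.random.default_rng(ss_flip)

    # --- stimulus set -----------------------------------------------------
    n_frames = frame_counts_for_set(spec.n_videos, spec.fps, spec.duration_s)
    conditions = ["lat"] * spec.n_lat + ["multi"] * spec.n_multi
    sides = (
        ["left"] * (spec.n_lat // 2) + ["right"] * (spec.n_lat // 2)
        + ["left"] * (spec.n_multi // 2) + ["right"] * (spec.n_multi // 2)
    )
    video_rows = []
    layouts: dict[str, GroundTruth] = {}
    video_seeds: dict[str, int] = {}
    video_rngs = ss_videos.spawn(spec.n_videos)
    for k, (cond, side) in enumerate(zip(conditions, sides)):
        vid = f"v{k:03d}"
        clutter = spec.clutter_mean_lat if cond == "lat" else spec.clutter_mean_multi
        truth = generate_scene_layout(
            cond, side, clutter, geometry, spec.fps,
            np.random.default_rng(video_rngs[k]),
            spec.duration_s, int(n_frames[k]),
        )
        layouts[vid] = truth
        video_rows.append(
            {
                "video_id": vid,
                "condition": cond,
                "side": truth.side,
                "sal_idx": truth.true_lateralization,
                "n_frames": int(n_frames[k]),
            }
        )
    videos = pd.DataFrame(video_rows)

    # --- flip balancing ---------------------------------------------------
    subjects = [f"s{j:02d}" for j in range(1, spec.n_subjects + 1)]
    if spec.n_subjects % 2:
        import warnings

        warnings.warn(
            "odd number of subjects: flip balancing uses the nearest split",
            stacklevel=2,
        )
    # Balanced flip assignment: within every condition x side cell, each
    # video is mirrored for half the subjects (circulant over a random
    # subject order), so each subject also views every cell half-mirrored
    # and the viewed condition x side counts stay balanced.
    flip_table = {}
    n_half = spec.n_subjects // 2
    for (_, _), cell in videos.groupby(["condition", "side"], sort=True):
        perm = rng_flip.permutation(spec.n_subjects)
        for k, vid in enumerate(cell["video_id"]):
            flipped = np.zeros(spec.n_subjects, dtype=bool)
            flipped[perm[(k * n_half + np.arange(n_half)) % spec.n_subjects]] = True
            flip_table[vid] = flipped

    noncompliant = set(subjects[-spec.n_noncompliant_subjects :]) if spec.n_noncompliant_subjects else set()

    # --- per-subject schedules and traces ---------------------------------
    sched_rngs = ss_sched.spawn(spec.n_subjects)
    trace_seeds = ss_trace.spawn(spec.n_subjects)
    all_trials = []
    traces: list[GazeTrace] = []
    for j, subject in enumerate(subjects):
        viewed = videos.copy()
        flips = np.array([flip_table[v][j] for v in videos["video_id"]])
        viewed.loc[flips, "side"] = viewed.loc[flips, "side"].map(
            {"left": "right", "right": "left"}
        )
        viewed.loc[flips, "sal_idx"] = -viewed.loc[flips, "sal_idx"]
        viewed["flipped"] = flips
        viewed["base_video_id"] = viewed["video_id"]
        viewed.loc[flips, "video_id"] = viewed.loc[flips, "video_id"] + "F"

        sched_seed = int(np.random.default_rng(sched_rngs[j]).integers(2**31))
        schedule = build_schedule(
            viewed, spec.n_runs, spec.iti_min_s, spec.iti_max_s, sched_seed, spec.duration_s
        )
        schedule = schedule.merge(
            viewed[["video_id", "base_video_id", "flipped", "sal_idx"]],
            on="video_id",
            how="left",
        )
        schedule.insert(0, "subject", subject)

        corrupt_p = (
            spec.noncompliant_corrupt_fraction
            if subject in noncompliant
            else spec.corrupt_fraction
        )
        rng_t = np.random.default_rng(trace_seeds[j])
        corrupted_flags = []
        for row in schedule.itertuples():
            truth = layouts[row.base_video_id]
            if row.flipped:
                truth = mirror_truth(truth)
            trace = generate_gaze_trace(
                {"condition": row.condition, "side": row.side, "sal_idx": row.sal_idx},
                truth,
                gaze_params,
                geometry,
                rng_t,
            )
            corrupted = rng_t.random() < corrupt_p
            if corrupted:
                mode = "off_center" if rng_t.random() < 0.5 else "blink_loss"
                trace = _corrupt_trace(trace, mode, rng_t)
            corrupted_flags.append(corrupted)
            traces.append(trace)
        schedule["corrupted"] = corrupted_flags
        all_trials.append(schedule)

    trials = pd.concat(all_trials, ignore_index=True)
    return CohortData(
        spec=spec,
        geometry=geometry,
        videos=videos,
        trials=trials,
        traces=traces,
        layouts=layouts,
        video_seeds=video_seeds,
    )
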