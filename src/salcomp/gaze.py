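"""Fixation parsing, trial/subject quality control and gaze lateralization.

Raw eye-tracking traces are timestamped (x, y) samples in degrees of visual
angle with a per-sample validity flag (False during blinks or tracker
dropout).  Fixations are detected with a dispersion-threshold algorithm
(I-DT): a maximal run of consecutive valid samples whose per-axis range
stays within ``dispersion_deg`` and whose sampled duration reaches
``min_duration_s`` is one fixation.  Durations are counted as
``n_samples / sampling_hz`` with an inclusive threshold, so at 120 Hz a
12-sample dwell qualifies as a 100 ms fixation and an 11-sample dwell does
not.

The gaze lateralization index accumulates valid stimulus-period samples
left/right of a central exclusion band and is signed so that **positive
values indicate a rightward bias**:
``gaze_idx = (Rtime - Ltime) / (Rtime + Ltime)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, DEFAULT_GEOMETRY

__all__ = [
    "GazeTrace",
    "Fixation",
    "QCResult",
    "HemifieldGaze",
    "detect_fixations",
    "count_saccades",
    "trial_qc",
    "select_valid_subjects",
    "gaze_lateralization_index",
    "saccade_rate_by_condition",
]


@dataclass
class GazeTrace:
    """Uniformly sampled gaze recording for one trial.

    ``time_s`` is strictly increasing; ``valid`` is False for blink /
    dropout samples.  ``stimulus_onset_s`` marks video onset within the
    trace (samples before it form the pre-stimulus window).
    """

    time_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    sampling_hz: float
    stimulus_onset_s: float = 0.0
    stimulus_duration_s: float = 1.5

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_s)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.valid) == n):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")

    def stimulus_slice(self) -> np.ndarray:
        """Boolean mask of samples within the stimulus period."""
        t0 = self.stimulus_onset_s
        return (self.time_s >= t0 - 1e-9) & (
            self.time_s < t0 + self.stimulus_duration_s - 1e-9
        )


@dataclass
class Fixation:
    """One dispersion-defined fixation.

    ``first_index``/``last_index`` are sample indices into the parent trace;
    the sampled duration is ``n_samples / sampling_hz`` and ``offset_s``
    extends one sampling interval past the last member sample so that
    ``offset_s - onset_s`` equals it.
    """

    onset_s: float
    offset_s: float
    centroid_x_deg: float
    centroid_y_deg: float
    first_index: int
    last_index: int

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def n_samples(self) -> int:
        return self.last_index - self.first_index + 1


@dataclass
class QCResult:
    """Outcome of the per-trial eye-trace quality control."""

    passed: bool
    reasons: list[str] = field(default_factory=list)
    prestim_x_deg: float = float("nan")
    prestim_y_deg: float = float("nan")
    fixation_fraction: float = 0.0


@dataclass
class HemifieldGaze:
    """Looking time per hemifield and the gaze lateralization index."""

    ltime_s: float
    rtime_s: float
    gaze_idx: float
    defined: bool


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (half-open) of maximal valid runs."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_fixations(
    trace: GazeTrace,
    dispersion_deg: float = 1.5,
    min_duration_s: float = 0.100,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Scans each maximal run of valid samples left to right: from the current
    start the window is extended while both the x-range and the y-range stay
    within ``dispersion_deg``; if the resulting maximal window reaches
    ``min_duration_s`` (inclusive, counting ``n / sampling_hz``) it is
    emitted as a fixation and the scan resumes after it, otherwise the start
    advances by one sample.  Invalid samples terminate candidate windows.
    """
    if len(trace.time_s) == 0:
        return []
    dt = 1.0 / trace.sampling_hz
    min_n = int(np.ceil(min_duration_s * trace.sampling_hz - 1e-9))
    x, y = trace.x_deg, trace.y_deg
    fixations: list[Fixation] = []
    for start, stop in _valid_runs(trace.valid):
        i = start
        while i < stop:
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            j = i + 1
            while j < stop:
                nxmin, nxmax = min(xmin, x[j]), max(xmax, x[j])
                nymin, nymax = min(ymin, y[j]), max(ymax, y[j])
                if nxmax - nxmin > dispersion_deg or nymax - nymin > dispersion_deg:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            n = j - i
            if n >= min_n:
                fixations.append(
                    Fixation(
                        onset_s=float(trace.time_s[i]),
                        offset_s=float(trace.time_s[j - 1]) + dt,
                        centroid_x_deg=float(x[i:j].mean()),
                        centroid_y_deg=float(y[i:j].mean()),
                        first_index=i,
                        last_index=j - 1,
                    )
                )
                i = j
            else:
                i += 1
    return fixations


def count_saccades(fixations: list[Fixation]) -> int:
    """Number of saccades = number of fixations minus one, clamped at 0."""
    return max(len(fixations) - 1, 0)


def trial_qc(
    trace: GazeTrace,
    prestim_window_s: float = 0.200,
    max_offset_deg: float = 2.0,
    min_fixation_fraction: float = 0.5,
    dispersion_deg: float = 1.5,
    min_duration_s: float = 0.100,
) -> QCResult:
    """Per-trial eye-trace quality control.

    Fails with ``off_center_prestim`` when the mean valid gaze position in
    the ``prestim_window_s`` before stimulus onset lies more than
    ``max_offset_deg`` from the centre on either axis (or when no valid
    pre-stimulus sample exists), and with ``low_fixation_fraction`` when
    fewer than ``min_fixation_fraction`` of the stimulus-period samples
    (valid or not) belong to detected fixations.
    """
    t0 = trace.stimulus_onset_s
    pre = (trace.time_s >= t0 - prestim_window_s - 1e-9) & (trace.time_s < t0 - 1e-9)
    pre_valid = pre & trace.valid
    reasons: list[str] = []
    if not pre_valid.any():
        px = py = float("nan")
        reasons.append("off_center_prestim")
    else:
        px = float(trace.x_deg[pre_valid].mean())
        py = float(trace.y_deg[pre_valid].mean())
        if abs(px) > max_offset_deg or abs(py) > max_offset_deg:
            reasons.append("off_center_prestim")

    stim = trace.stimulus_slice()
    n_stim = int(stim.sum())
    if n_stim == 0:
        fraction = 0.0
    else:
        fixations = detect_fixations(trace, dispersion_deg, min_duration_s)
        member = np.zeros(len(trace.time_s), dtype=bool)
        for fix in fixations:
            member[fix.first_index : fix.last_index + 1] = True
        fraction = float((member & stim).sum()) / n_stim
    if fraction < min_fixation_fraction:
        reasons.append("low_fixation_fraction")

    return QCResult(
        passed=not reasons,
        reasons=reasons,
        prestim_x_deg=px,
        prestim_y_deg=py,
        fixation_fraction=fraction,
    )


def select_valid_subjects(
    qc_table: pd.DataFrame, min_per_condition: int = 6
) -> list:
    """Subjects with at least ``min_per_condition`` QC-passing trials in
    every condition cell.

    ``qc_table`` needs columns ``subject``, ``condition``, ``side`` and
    ``qc_pass``; the four cells are condition x side.
    """
    required = {"subject", "condition", "side", "qc_pass"}
    if not required.issubset(qc_table.columns):
        raise ValueError(f"qc_table must have columns {sorted(required)}")
    cells = (
        qc_table[qc_table["qc_pass"]]
        .groupby(["subject", "condition", "side"])
        .size()
        .unstack(["condition", "side"], fill_value=0)
    )
    n_cells = qc_table.groupby(["condition", "side"]).ngroups
    kept = []
    for subject, row in cells.iterrows():
        if len(row) == n_cells and (row >= min_per_condition).all():
            kept.append(subject)
    return kept


def gaze_lateralization_index(
    trace: GazeTrace, geometry: ScreenGeometry | None = None
) -> HemifieldGaze:
    """Hemifield looking times and ``gaze_idx = (R - L) / (R + L)``.

    Valid stimulus-period samples with x left of the central band accrue to
    ``Ltime`` and right of it to ``Rtime`` (one sampling interval each);
    samples inside the band are ignored.  Undefined (NaN, flagged) when no
    off-centre time was accumulated.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    dt = 1.0 / trace.sampling_hz
    sel = trace.stimulus_slice() & trace.valid
    x = trace.x_deg[sel]
    c = geometry.central_exclusion_deg
    ltime = float((x < -c).sum()) * dt
    rtime = float((x > c).sum()) * dt
    total = ltime + rtime
    if total <= 0.0:
        return HemifieldGaze(ltime_s=ltime, rtime_s=rtime, gaze_idx=float("nan"), defined=False)
    return HemifieldGaze(
        ltime_s=ltime, rtime_s=rtime, gaze_idx=(rtime - ltime) / total, defined=True
    )


def saccade_rate_by_condition(
    trials: pd.DataFrame, duration_s: float = 1.5
) -> pd.DataFrame:
    """Mean saccade rate (saccades/s) per subject and condition.

    Expects columns ``subject``, ``condition`` and ``saccade_count``; only
    QC-passing trials should be passed in.  Returns a tidy frame with one
    row per (subject, condition).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    out = (
        trials.groupby(["subject", "condition"])["saccade_count"]
        .mean()
        .div(duration_s)
        .rename("saccade_rate_hz")
        .reset_index()
    )
    return out
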