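"""End-to-end behavioural pipeline: traces -> trial metrics -> statistics.

Glue between the gaze parsing, subject selection and statistics modules,
operating on the tidy trial table produced by the cohort simulator (or
loaded from CSV) plus the matching list of gaze traces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, DEFAULT_GEOMETRY
from .gaze import (
    GazeTrace,
    count_saccades,
    detect_fixations,
    gaze_lateralization_index,
    saccade_rate_by_condition,
    select_valid_subjects,
    trial_qc,
)
from .stats import condition_correlations, paired_t

__all__ = ["annotate_trials", "behavioral_summary"]


def annotate_trials(
    trials: pd.DataFrame,
    traces: list[GazeTrace],
    geometry: ScreenGeometry | None = None,
    dispersion_deg: float = 1.5,
    min_duration_s: float = 0.100,
) -> pd.DataFrame:
    """Add per-trial QC outcome, gaze index and saccade count.

    ``traces`` must be aligned with the rows of ``trials``.  Saccades are
    counted over fixations whose onset falls inside the stimulus window.
    Returns a copy of ``trials`` with columns ``qc_pass``,
    ``fixation_fraction``, ``gaze_idx`` (NaN when undefined) and
    ``saccade_count``.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    if len(traces) != len(trials):
        raise ValueError("need exactly one trace per trial row")
    out = trials.copy()
    qc_pass, frac, gaze_idx, sac = [], [], [], []
    for trace in traces:
        qc = trial_qc(trace, dispersion_deg=dispersion_deg, min_duration_s=min_duration_s)
        qc_pass.append(qc.passed)
        frac.append(qc.fixation_fraction)
        hemi = gaze_lateralization_index(trace, geometry)
        gaze_idx.append(hemi.gaze_idx if hemi.defined else np.nan)
        fixes = detect_fixations(trace, dispersion_deg, min_duration_s)
        t0 = trace.stimulus_onset_s
        t1 = t0 + trace.stimulus_duration_s
        in_window = [f for f in fixes if t0 - 1e-9 <= f.onset_s < t1 - 1e-9]
        sac.append(count_saccades(in_window))
    out["qc_pass"] = qc_pass
    out["fixation_fraction"] = frac
    out["gaze_idx"] = gaze_idx
    out["saccade_count"] = sac
    return out


def behavioral_summary(annotated: pd.DataFrame, duration_s: float = 1.5) -> dict:
    """Subject selection, condition-wise correlations and the saccade-rate
    contrast, computed from an annotated trial table.

    Returns a dict with the retained subjects, one correlation result per
    condition x side cell (QC-passing trials of retained subjects only),
    the per-subject condition saccade rates and the paired t-test of lat vs
    multi rates.
    """
    retained = select_valid_subjects(annotated)
    good = annotated[annotated["qc_pass"] & annotated["subject"].isin(retained)]
    correlations = condition_correlations(good)
    rates = saccade_rate_by_condition(good, duration_s)
    wide = rates.pivot(index="subject", columns="condition", values="saccade_rate_hz")
    if {"lat", "multi"}.issubset(wide.columns) and len(wide.dropna()) >= 2:
        both = wide.dropna()
        rate_test = paired_t(both["multi"], both["lat"])
    else:
        rate_test = None
    return {
        "retained_subjects": retained,
        "correlations": correlations,
        "saccade_rates": rates,
        "saccade_rate_paired_t": rate_test,
    }
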