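"""Shared fixtures: small synthetic cohorts and reusable traces."""

from __future__ import annotations

import numpy as np
import pytest

from salcomp.geometry import ScreenGeometry
from salcomp.gaze import GazeTrace
from salcomp.synthetic import CohortSpec, GazeModelParams, generate_cohort


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced clean cohort (no corruption) shared across tests."""
    spec = CohortSpec(
        n_subjects=4,
        n_videos=24,
        n_lat=12,
        n_multi=12,
        corrupt_fraction=0.0,
        n_noncompliant_subjects=0,
    )
    return generate_cohort(spec, GazeModelParams(blink_prob_per_s=0.0), seed=11)


def make_trace(
    x,
    y=None,
    hz: float = 120.0,
    valid=None,
    onset_s: float = 0.0,
    duration_s: float = 1.5,
) -> GazeTrace:
    """Build a trace from raw sample arrays (helper for hand-made cases)."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return GazeTrace(
        time_s=np.arange(len(x)) / hz,
        x_deg=x,
        y_deg=y,
        valid=valid,
        sampling_hz=hz,
        stimulus_onset_s=onset_s,
        stimulus_duration_s=duration_s,
    )
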