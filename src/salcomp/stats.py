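"""Behavioural statistics: condition-wise correlations, t-tests, scaling.

Thin, explicitly-typed wrappers around the scipy test routines with the
degenerate cases (zero variance, too-few observations) flagged instead of
silently returning NaN.  All p-values are two-tailed and no
multiple-comparison correction is applied across the four behavioural
correlation cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "pearson_r_p",
    "condition_correlations",
    "paired_t",
    "two_sample_t_pooled",
    "one_sample_t",
    "scale_unit_interval",
]


@dataclass
class CorrelationResult:
    """Pearson correlation for one condition cell (df = n - 2)."""

    condition: str
    n: int
    r: float
    p: float
    defined: bool = True


@dataclass
class TTestResult:
    statistic: float
    df: int
    p: float
    kind: str  # 'paired' | 'two_sample_pooled' | 'one_sample'
    defined: bool = True


def _as_finite(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def pearson_r_p(x, y, condition: str = "") -> CorrelationResult:
    """Sample Pearson r with a two-tailed p from the t transform (n-2 df).

    Zero variance in either variable yields an undefined (flagged) result.
    """
    x = _as_finite(x, "x")
    y = _as_finite(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(condition, n, float("nan"), float("nan"), defined=False)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(condition, n, float(r), float(p))


def condition_correlations(
    trials: pd.DataFrame,
    sal_col: str = "sal_idx",
    gaze_col: str = "gaze_idx",
) -> dict[str, CorrelationResult]:
    """Per-cell correlation between per-video salience and gaze indexes.

    ``trials`` holds QC-passing trials with columns ``video_id``,
    ``condition``, ``side``, ``sal_idx`` and ``gaze_idx`` (one row per
    subject x video; the per-video gaze index is the mean over subjects).
    Returns one result per condition x side cell, keyed like ``"Rmulti"``.
    Cells with fewer than 3 videos are undefined.
    """
    out: dict[str, CorrelationResult] = {}
    df = trials.dropna(subset=[gaze_col, sal_col])
    for (condition, side), cell in df.groupby(["condition", "side"], sort=True):
        key = f"{side[0].upper()}{condition}"
        per_video = cell.groupby("video_id").agg({sal_col: "first", gaze_col: "mean"})
        if len(per_video) < 3:
            out[key] = CorrelationResult(key, len(per_video), float("nan"), float("nan"), defined=False)
            continue
        out[key] = pearson_r_p(per_video[sal_col], per_video[gaze_col], condition=key)
    return out


def paired_t(a, b) -> TTestResult:
    """Paired t-test on per-subject values (df = n - 1)."""
    a = _as_finite(a, "a")
    b = _as_finite(b, "b")
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:  # identical samples: no difference, trivially t = 0
            return TTestResult(0.0, n - 1, 1.0, "paired")
        return TTestResult(float("nan"), n - 1, float("nan"), "paired", defined=False)
    t, p = sps.ttest_rel(a, b)
    return TTestResult(float(t), n - 1, float(p), "paired")


def two_sample_t_pooled(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test (df = n_a + n_b - 2)."""
    a = _as_finite(a, "a")
    b = _as_finite(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return TTestResult(float("nan"), df, float("nan"), "two_sample_pooled", defined=False)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), df, float(p), "two_sample_pooled")


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test against ``mu0`` (df = n - 1)."""
    v = _as_finite(values, "values")
    if len(v) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(v) == 0:
        if v[0] == mu0:
            return TTestResult(0.0, len(v) - 1, 1.0, "one_sample")
        return TTestResult(float("nan"), len(v) - 1, float("nan"), "one_sample", defined=False)
    t, p = sps.ttest_1samp(v, mu0)
    return TTestResult(float(t), len(v) - 1, float(p), "one_sample")


def scale_unit_interval(values) -> np.ndarray:
    """Min-max scale a per-run list of values to [0, 1].

    Used to put parametric modulators on a common range before model
    fitting.  Raises for constant input, where the scale is undefined.
    """
    v = _as_finite(values, "values")
    if len(v) < 2 or np.ptp(v) == 0:
        raise ValueError("need at least two distinct values to scale")
    return (v - v.min()) / np.ptp(v)
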