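"""Condition bookkeeping for the behavioural and decoding analyses.

Covers Left/Right categorization of stimuli from the salience
lateralization index, randomized trial scheduling with uniform inter-trial
intervals, the pseudo-random split of each run x condition cell into three
sub-groups (the per-regressor grouping used to obtain 24 beta images per
subject), and the leave-one-set-out cross-validation folds over those 24
images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("lat", "multi")
SIDES = ("left", "right")

__all__ = [
    "CONDITIONS",
    "SIDES",
    "SubGroupAssignment",
    "FoldSpec",
    "assign_side",
    "build_schedule",
    "split_subgroups",
    "build_folds",
]


@dataclass
class SubGroupAssignment:
    """Sub-group labels (1..3) for the trials of one run.

    ``table`` is the input trial table with an added ``subgroup`` column;
    ``violations`` lists any balance constraints the bounded search could
    not satisfy exactly (best-effort assignment).
    """

    table: pd.DataFrame
    violations: list[str] = field(default_factory=list)


@dataclass
class FoldSpec:
    """Leave-one-image-set-out folds over 24 labelled beta images.

    Each of the six image-sets (run x sub-group) contains one beta per
    condition; fold *g* trains on the other five sets (20 images) and tests
    on set *g* (4 images).  Indices refer to rows of the label table.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    set_ids: list[tuple[int, int]]  # (run, subgroup) per fold


def assign_side(sal_idx: float, seed: int = 0) -> str:
    """Categorize a stimulus as 'left' or 'right' from its sal_idx.

    Positive sal_idx (rightward salience bias) maps to 'right'.  An exact
    zero is broken by a seeded coin flip and logged.
    """
    if sal_idx is None or not np.isfinite(sal_idx):
        raise ValueError("sal_idx is undefined; cannot assign a side")
    if sal_idx > 0:
        return "right"
    if sal_idx < 0:
        return "left"
    choice = "right" if np.random.default_rng(seed).random() < 0.5 else "left"
    logger.info("sal_idx == 0: tie broken to %r (seed=%d)", choice, seed)
    return choice


def build_schedule(
    videos: pd.DataFrame,
    n_runs: int = 2,
    iti_min_s: float = 3.0,
    iti_max_s: float = 7.4,
    seed: int = 0,
    duration_s: float = 1.5,
) -> pd.DataFrame:
    """Randomized trial schedule balanced over runs.

    ``videos`` needs columns ``video_id``, ``condition`` and ``side``.  The
    videos of each condition x side cell are dealt evenly (+-1) across
    ``n_runs`` runs, order within a run is random, and onsets are spaced by
    the stimulus duration plus ITIs drawn uniformly from
    [``iti_min_s``, ``iti_max_s``].
    """
    if len(videos) == 0:
        raise ValueError("videos table is empty")
    if n_runs > len(videos):
        raise ValueError("more runs than videos")
    if iti_min_s > iti_max_s or iti_min_s < 0:
        raise ValueError("invalid ITI range")
    rng = np.random.default_rng(seed)
    run_members: list[list[int]] = [[] for _ in range(n_runs)]
    for (_, _), cell in videos.groupby(["condition", "side"], sort=True):
        idx = cell.index.to_numpy()
        rng.shuffle(idx)
        start = int(rng.integers(n_runs))  # rotate which run gets the remainder
        for k, i in enumerate(idx):
            run_members[(start + k) % n_runs].append(i)
    rows = []
    for run, members in enumerate(run_members, start=1):
        order = np.array(members)
        rng.shuffle(order)
        onset = 0.0
        for i in order:
            onset += float(rng.uniform(iti_min_s, iti_max_s))
            rows.append(
                {
                    "video_id": videos.at[i, "video_id"],
                    "run": run,
                    "onset_s": onset,
                    "condition": videos.at[i, "condition"],
                    "side": videos.at[i, "side"],
                }
            )
            onset += duration_s
    return pd.DataFrame(rows)


def _near_equal_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _balance_score(groups: list[np.ndarray], categories: np.ndarray) -> int:
    """Total excess over max-min <= 1 balance, per category, across groups."""
    score = 0
    for cat in np.unique(categories):
        counts = [int(np.sum(categories[g] == cat)) for g in groups]
        score += max(0, max(counts) - min(counts) - 1)
    return score


def split_subgroups(
    run_trials: pd.DataFrame,
    seed: int = 0,
    n_subgroups: int = 3,
    max_restarts: int = 40,
    max_sweeps: int = 60,
) -> SubGroupAssignment:
    """Pseudo-random split of each condition cell of one run into sub-groups.

    Trials must be ordered by onset and carry ``condition``, ``side`` and
    ``onset_s``.  Within each condition x side cell the sub-groups are of
    near-equal size and the assignment is searched (seeded randomized
    restarts with pairwise-swap repair) so that, per cell:

    * each sub-group has an equal (+-1) number of trials from the first and
      the second half of the run (split at the median onset), and
    * the previous-trial condition categories are spread across the
      sub-groups as evenly as integer counts allow (max - min <= 1).

    When the bounded search cannot zero the residual imbalance the best
    assignment found is returned and the violations are reported.
    """
    df = run_trials.reset_index(drop=True).copy()
    if not df["onset_s"].is_monotonic_increasing:
        raise ValueError("run trials must be ordered by onset")
    rng = np.random.default_rng(seed)
    cond4 = df["condition"].astype(str) + "_" + df["side"].astype(str)
    prev_cat = np.concatenate([["<start>"], cond4.to_numpy()[:-1]])
    first_half = (df["onset_s"] <= df["onset_s"].median()).to_numpy()
    subgroup = np.zeros(len(df), dtype=int)
    violations: list[str] = []

    for cell_name in sorted(cond4.unique()):
        cell_idx = np.flatnonzero(cond4.to_numpy() == cell_name)
        sizes = _near_equal_sizes(len(cell_idx), n_subgroups)
        half_cat = first_half[cell_idx].astype(int)
        prev_cell = prev_cat[cell_idx]

        def score_of(assign: np.ndarray) -> int:
            groups = [np.flatnonzero(assign == g) for g in range(n_subgroups)]
            return _balance_score(groups, half_cat) + _balance_score(groups, prev_cell)

        best_assign, best_score = None, None
        for _ in range(max_restarts):
            assign = np.repeat(np.arange(n_subgroups), sizes)
            rng.shuffle(assign)
            score = score_of(assign)
            for _ in range(max_sweeps):
                if score == 0:
                    break
                i, j = rng.integers(len(assign)), rng.integers(len(assign))
                if assign[i] == assign[j]:
                    continue
                assign[i], assign[j] = assign[j], assign[i]
                new_score = score_of(assign)
                if new_score <= score:
                    score = new_score
                else:
                    assign[i], assign[j] = assign[j], assign[i]
            if best_score is None or score < best_score:
                best_assign, best_score = assign.copy(), score
            if best_score == 0:
                break
        subgroup[cell_idx] = best_assign + 1
        if best_score and best_score > 0:
            msg = f"cell {cell_name}: residual balance excess {best_score}"
            violations.append(msg)
            logger.warning("split_subgroups: %s", msg)

    df["subgroup"] = subgroup
    return SubGroupAssignment(table=df, violations=violations)


def build_folds(beta_labels: pd.DataFrame) -> FoldSpec:
    """Leave-one-image-set-out folds from 24 labelled beta images.

    ``beta_labels`` needs columns ``run`` (1..2), ``condition`` ('lat' /
    'multi'), ``side`` ('left'/'right') and ``subgroup`` (1..3), with each
    of the 24 combinations appearing exactly once.  Image-set *g* is the
    (run, subgroup) pair; each fold tests the 4 images of one set and
    trains on the remaining 20.
    """
    required = {"run", "condition", "side", "subgroup"}
    if not required.issubset(beta_labels.columns):
        raise ValueError(f"beta label table must have columns {sorted(required)}")
    if len(beta_labels) != 24:
        raise ValueError(f"expected 24 beta labels, got {len(beta_labels)}")
    expected = {
        (r, c, s, g)
        for r, (c, s), g in product((1, 2), product(CONDITIONS, SIDES), (1, 2, 3))
    }
    observed = {
        (int(row.run), str(row.condition), str(row.side), int(row.subgroup))
        for row in beta_labels.itertuples()
    }
    if observed != expected:
        raise ValueError("beta labels must cover 2 runs x 4 conditions x 3 sub-groups exactly once")

    runs = beta_labels["run"].to_numpy(dtype=int)
    groups = beta_labels["subgroup"].to_numpy(dtype=int)
    folds = []
    set_ids = []
    for run, sg in product((1, 2), (1, 2, 3)):
        test = np.flatnonzero((runs == run) & (groups == sg))
        train = np.flatnonzero((runs != run) | (groups != sg))
        folds.append((train, test))
        set_ids.append((run, sg))
    return FoldSpec(folds=folds, set_ids=set_ids)
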