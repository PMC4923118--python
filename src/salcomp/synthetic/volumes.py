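"""Synthetic beta volumes for the searchlight-decoding scaffold.

Stands in for first-level GLM parameter estimates: per subject, 24 labelled
volumes (2 runs x 4 conditions x 3 sub-groups) of Gaussian noise, with a
fixed multivariate pattern added inside an informative region to every
multi-condition volume.  The pattern is shared across subjects (so group
inference has a true effect to find) and scaled by ``effect_amplitude``;
amplitude 0 yields pure-noise null data.  A companion gray-matter
probability map covers a configurable central fraction of the grid.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from ..decoding import BetaImageSet
from ..design import CONDITIONS, SIDES

__all__ = ["default_informative_region", "generate_beta_volumes"]


def default_informative_region(grid_dims: tuple[int, int, int], radius: float = 3.0) -> np.ndarray:
    """Spherical region in the grid centre (boolean mask)."""
    grids = np.meshgrid(*[np.arange(d) - (d - 1) / 2.0 for d in grid_dims], indexing="ij")
    return sum(g**2 for g in grids) <= radius**2


def _beta_labels() -> pd.DataFrame:
    rows = [
        {"run": r, "condition": c, "side": s, "subgroup": g}
        for r, (c, s), g in product((1, 2), product(CONDITIONS, SIDES), (1, 2, 3))
    ]
    return pd.DataFrame(rows)


def generate_beta_volumes(
    n_subjects: int,
    grid_dims: tuple[int, int, int] = (16, 16, 16),
    effect_amplitude: float = 1.0,
    informative_region: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    gm_fraction: float = 0.7,
) -> tuple[list[BetaImageSet], np.ndarray]:
    """Generate per-subject beta image sets and a gray-matter probability map.

    Returns ``(betas, gm_prob)`` where each element of ``betas`` holds 24
    volumes with labels (run, condition, side, subgroup) and ``gm_prob`` is
    a probability map equal to 0.9 inside a central box covering about
    ``gm_fraction`` of the grid and 0 outside.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if any(d < 10 for d in grid_dims):
        raise ValueError("grid dimensions must each be >= 10")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if informative_region is None:
        informative_region = default_informative_region(grid_dims)
    informative_region = np.asarray(informative_region, dtype=bool)
    if informative_region.shape != grid_dims:
        raise ValueError("informative_region must match grid_dims")
    if not informative_region.any():
        raise ValueError("informative_region is empty")

    root = np.random.SeedSequence(seed)
    ss_pattern, *ss_subjects = root.spawn(1 + n_subjects)
    pattern = np.random.default_rng(ss_pattern).standard_normal(int(informative_region.sum()))

    labels = _beta_labels()
    is_multi = (labels["condition"] == "multi").to_numpy()
    betas = []
    for j in range(n_subjects):
        rng = np.random.default_rng(ss_subjects[j])
        data = rng.normal(0.0, noise_sd, size=(24, *grid_dims))
        for v in np.flatnonzero(is_multi):
            vol = data[v]
            vol[informative_region] += effect_amplitude * pattern
        betas.append(BetaImageSet(data=data, labels=labels.copy(), subject=f"s{j + 1:02d}"))

    side = [int(round(d * gm_fraction ** (1 / 3))) for d in grid_dims]
    gm = np.zeros(grid_dims)
    slices = tuple(
        slice((d - s) // 2, (d - s) // 2 + s) for d, s in zip(grid_dims, side)
    )
    gm[slices] = 0.9
    return betas, gm
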