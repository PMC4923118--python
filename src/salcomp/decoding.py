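"""Searchlight decoding of condition (multi vs lat) from beta volumes.

A binary linear classifier is trained and tested inside a spherical
neighbourhood moved over every gray-matter voxel.  For each sphere centre
the six leave-one-image-set-out folds are evaluated, the 24 pooled test
decisions give one accuracy, and the map stores accuracy minus the 50%
binary chance level in percentage points.  Spheres are truncated (not
skipped) at mask edges.  Group-level inference is a voxel-wise one-sample
t-test of the per-subject accuracy-minus-chance maps against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

from .design import FoldSpec

__all__ = [
    "GrayMatterMask",
    "BetaImageSet",
    "threshold_gray_matter",
    "sphere_offsets",
    "sphere_membership",
    "searchlight_decode",
    "group_accuracy_inference",
]


@dataclass
class GrayMatterMask:
    """Boolean voxel mask derived from a tissue probability map."""

    mask: np.ndarray  # boolean, 3D
    threshold: float
    n_voxels: int


@dataclass
class BetaImageSet:
    """24 condition-labelled beta volumes of one subject.

    ``data`` is (24, X, Y, Z); ``labels`` carries one row per volume with
    columns ``run``, ``condition`` ('lat'/'multi'), ``side`` and
    ``subgroup``.
    """

    data: np.ndarray
    labels: pd.DataFrame
    subject: str = ""


def threshold_gray_matter(prob_map: np.ndarray, threshold: float = 0.10) -> GrayMatterMask:
    """Strict-greater-than threshold of a tissue probability map."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    mask = prob_map > threshold
    n = int(mask.sum())
    if n == 0:
        raise ValueError("gray-matter mask is empty at this threshold")
    return GrayMatterMask(mask=mask, threshold=threshold, n_voxels=n)


def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """Integer offsets with squared Euclidean distance <= radius^2.

    For radius 4 this is 257 offsets (the interior searchlight size).
    """
    if radius_voxels < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius_voxels)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_membership(
    mask: GrayMatterMask | np.ndarray, radius_voxels: int = 4
) -> list[np.ndarray]:
    """Per-centre member lists for a searchlight over the mask.

    For every mask voxel (in ``np.argwhere`` order) the members are the
    in-mask voxels at integer offsets within the sphere radius, given as
    indices into the masked-voxel vector (same ordering).  Edge spheres are
    truncated, never skipped; the centre is always a member.
    """
    m = mask.mask if isinstance(mask, GrayMatterMask) else np.asarray(mask, dtype=bool)
    offsets = sphere_offsets(radius_voxels)
    coords = np.argwhere(m)
    vox_id = -np.ones(m.shape, dtype=int)
    vox_id[tuple(coords.T)] = np.arange(len(coords))
    members = []
    shape = np.array(m.shape)
    for c in coords:
        pts = c[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
        ids = vox_id[tuple(pts[ok].T)]
        members.append(np.sort(ids[ids >= 0]))
    return members


def _default_classifier():
    # deterministic maximum-margin linear classifier, fixed C, no scaling
    return SVC(kernel="linear", C=1.0)


def searchlight_decode(
    betas: BetaImageSet,
    folds: FoldSpec,
    mask: GrayMatterMask,
    spheres: list[np.ndarray] | None = None,
    radius_voxels: int = 4,
    classifier_factory=None,
) -> np.ndarray:
    """Cross-validated multi-vs-lat accuracy-minus-chance map.

    Returns a 3D float map with accuracy - 50 (percentage points) at mask
    voxels and NaN elsewhere.  Accuracy pools the 24 test decisions of the
    six folds; each volume is tested exactly once.
    """
    data = np.asarray(betas.data, dtype=float)
    if data.shape[0] != 24:
        raise ValueError("expected 24 beta volumes")
    if not np.all(np.isfinite(data)):
        raise ValueError("beta volumes contain non-finite values")
    if data.shape[1:] != mask.mask.shape:
        raise ValueError("beta volumes and mask are not aligned")
    if spheres is None:
        spheres = sphere_membership(mask, radius_voxels)
    factory = classifier_factory or _default_classifier

    y = betas.labels["condition"].to_numpy()
    if set(y) != {"lat", "multi"}:
        raise ValueError("labels must contain both 'lat' and 'multi'")
    X_all = data[:, mask.mask]  # (24, n_voxels)

    n_vox = X_all.shape[1]
    acc = np.zeros(n_vox)
    for i, member_ids in enumerate(spheres):
        X = X_all[:, member_ids]
        correct = 0
        for train, test in folds.folds:
            clf = factory()
            clf.fit(X[train], y[train])
            correct += int(np.sum(clf.predict(X[test]) == y[test]))
        acc[i] = 100.0 * correct / 24.0 - 50.0

    out = np.full(mask.mask.shape, np.nan)
    out[mask.mask] = acc
    return out


def group_accuracy_inference(
    accuracy_maps: list[np.ndarray], mask: GrayMatterMask
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise one-sample t-test of accuracy-minus-chance maps vs 0.

    Returns (t_map, p_map) with df = n_subjects - 1 and uncorrected
    two-tailed p-values; voxels with zero between-subject variance are NaN.
    """
    if len(accuracy_maps) < 2:
        raise ValueError("need at least 2 subjects")
    stack = np.stack([m[mask.mask] for m in accuracy_maps], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    n = stack.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    t_map = np.full(mask.mask.shape, np.nan)
    p_map = np.full(mask.mask.shape, np.nan)
    t_map[mask.mask] = t
    p_map[mask.mask] = p
    return t_map, p_map
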