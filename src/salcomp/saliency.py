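"""Multi-channel visual saliency maps and hemifield lateralization.

The saliency model follows the classic biologically-inspired architecture:
low-level feature maps (intensity, colour opponency, oriented contrast,
flicker and motion) are passed through a bank of centre-surround
difference-of-Gaussians operators, each resulting feature map is rescaled by
a max-based normalization operator that promotes maps with few isolated
peaks, and the per-channel conspicuity maps are averaged into the final
saliency map.

Two conventions matter downstream and are fixed here:

* Centre-surround responses are half-wave rectified (``max(c - s, 0)``),
  which gives every isolated object a compact region of strictly positive
  saliency surrounded by exact zeros.  Connected components of the
  time-summed map therefore correspond to distinct salient objects.
* The salience lateralization index ``sal_idx`` is signed so that
  **positive values indicate a rightward bias**:
  ``sal_idx = (R - L) / (R + L)`` with ``L``/``R`` the mean saliency in the
  left/right hemifield outside a central exclusion band.

The whole filter bank is mirror-symmetric, so horizontally flipping a frame
mirrors its saliency map exactly and negates ``sal_idx``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gabor_kernel

from .geometry import ScreenGeometry, DEFAULT_GEOMETRY

__all__ = [
    "SaliencyConfig",
    "ChannelSet",
    "SaliencyVideo",
    "HemifieldSalience",
    "frame_saliency",
    "video_saliency",
    "summed_saliency_map",
    "count_saliency_clusters",
    "salience_lateralization_index",
    "fixation_cluster_overlap",
]


@dataclass(frozen=True)
class SaliencyConfig:
    """Tunable parameters of the saliency bank.

    ``center_sigmas_deg`` are the centre scales of the difference-of-Gaussians
    operators (degrees of visual angle); each is paired with a surround of
    ``surround_ratio`` times its width.  The orientation channel uses four
    Gabor filters at 0/45/90/135 degrees (a mirror-symmetric set).
    ``clamp_rel`` is the relative floor below which summed-map values are
    clamped to exact zero before cluster labelling.
    """

    center_sigmas_deg: tuple[float, ...] = (0.3, 0.6)
    surround_ratio: float = 4.0
    gabor_frequency_cpp: float = 0.2  # cycles per pixel
    gabor_sigma_px: float = 3.0
    local_max_size_px: int = 9
    local_max_floor: float = 0.05
    clamp_rel: float = 1e-6
    degrees_per_px: float = DEFAULT_GEOMETRY.degrees_per_px

    def cs_pairs_px(self) -> list[tuple[float, float]]:
        return [
            (s / self.degrees_per_px, self.surround_ratio * s / self.degrees_per_px)
            for s in self.center_sigmas_deg
        ]


@dataclass
class ChannelSet:
    """Per-channel conspicuity maps (all non-negative, frame-shaped)."""

    intensity: np.ndarray
    color: np.ndarray
    orientation: np.ndarray
    motion: np.ndarray
    flicker: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "intensity": self.intensity,
            "color": self.color,
            "orientation": self.orientation,
            "motion": self.motion,
            "flicker": self.flicker,
        }


@dataclass
class SaliencyVideo:
    """Per-frame saliency maps plus the time-summed map and its clusters."""

    maps: np.ndarray  # (n_frames, H, W), non-negative
    summed_map: np.ndarray  # (H, W)
    labels: np.ndarray  # int labels of summed-map clusters, 0 = background
    n_clusters: int


@dataclass
class HemifieldSalience:
    """Hemifield-mean saliency and the lateralization index.

    ``sal_idx`` is NaN (and ``defined`` False) when both hemifield means are
    zero, in which case no lateralization is measurable.
    """

    left: float
    right: float
    sal_idx: float
    defined: bool


_GABOR_CACHE: dict[tuple[float, float], list[np.ndarray]] = {}


def _gabor_bank(config: SaliencyConfig) -> list[np.ndarray]:
    key = (config.gabor_frequency_cpp, config.gabor_sigma_px)
    if key not in _GABOR_CACHE:
        kernels = []
        for theta_deg in (0.0, 45.0, 90.0, 135.0):
            k = np.real(
                gabor_kernel(
                    config.gabor_frequency_cpp,
                    theta=np.deg2rad(theta_deg),
                    sigma_x=config.gabor_sigma_px,
                    sigma_y=config.gabor_sigma_px,
                )
            )
            kernels.append(k - k.mean())  # zero DC: uniform regions respond 0
        _GABOR_CACHE[key] = kernels
    return _GABOR_CACHE[key]


def _normalize_map(m: np.ndarray, config: SaliencyConfig) -> np.ndarray:
    """Max-based normalization: rescale to peak 1, then weight by (1 - mbar)^2.

    ``mbar`` is the mean of the non-global local maxima, so maps with one
    dominant peak are promoted and maps with many similar peaks suppressed.
    The operator is mirror-equivariant.
    """
    peak = float(m.max())
    if peak <= 0.0:
        return np.zeros_like(m)
    m = m / peak
    is_max = (m == ndi.maximum_filter(m, size=config.local_max_size_px, mode="reflect"))
    vals = m[is_max & (m > config.local_max_floor)]
    if vals.size <= 1:
        weight = 1.0
    else:
        # one of the local maxima is the global one (value 1.0)
        mbar = (float(vals.sum()) - 1.0) / (vals.size - 1)
        weight = (1.0 - mbar) ** 2
    return m * weight


def _center_surround(feat: np.ndarray, config: SaliencyConfig) -> list[np.ndarray]:
    out = []
    for sc, ss in config.cs_pairs_px():
        c = ndi.gaussian_filter(feat, sc, mode="reflect", truncate=3.0)
        s = ndi.gaussian_filter(feat, ss, mode="reflect", truncate=3.0)
        out.append(np.maximum(c - s, 0.0))
    return out


def _channel_conspicuity(feature_maps: list[np.ndarray], config: SaliencyConfig) -> np.ndarray:
    scale_maps: list[np.ndarray] = []
    for f in feature_maps:
        scale_maps.extend(_normalize_map(m, config) for m in _center_surround(f, config))
    return _normalize_map(np.sum(scale_maps, axis=0), config)


def _shift_edge(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift with edge replication (mirror-safe, no wrap-around)."""
    pad = np.pad(img, 1, mode="edge")
    return pad[1 + dr : 1 + dr + img.shape[0], 1 + dc : 1 + dc + img.shape[1]]


def frame_saliency(
    frame: np.ndarray,
    prev_frame: np.ndarray | None = None,
    config: SaliencyConfig | None = None,
) -> tuple[np.ndarray, ChannelSet]:
    """Compute the saliency map of one colour frame.

    Parameters
    ----------
    frame
        (H, W, 3) array with values in [0, 1].
    prev_frame
        Previous frame of the video, used for the flicker and motion
        channels; when absent (first frame) both channels are identically
        zero.
    config
        Saliency bank parameters; defaults to :class:`SaliencyConfig`.

    Returns
    -------
    (saliency, channels)
        ``saliency`` is the (H, W) non-negative final map (mean of the five
        channel conspicuity maps); ``channels`` holds the per-channel maps.
    """
    config = config or SaliencyConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be (H, W, 3)")
    if prev_frame is not None:
        prev_frame = np.asarray(prev_frame, dtype=float)
        if prev_frame.shape != frame.shape:
            raise ValueError("prev_frame shape must match frame")

    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    intensity = frame.mean(axis=-1)

    # double-opponent colour contrasts (non-negative by construction)
    rg = np.abs(r - g)
    by = np.abs(b - (r + g) / 2.0)

    orient_feats = [
        np.abs(ndi.convolve(intensity, k, mode="reflect")) for k in _gabor_bank(config)
    ]

    shape = intensity.shape
    if prev_frame is None:
        flick_feats = [np.zeros(shape)]
        motion_feats = [np.zeros(shape)] * 4
    else:
        prev_i = prev_frame.mean(axis=-1)
        flick_feats = [np.abs(intensity - prev_i)]
        # Reichardt-style shifted correlation: exactly zero for a static scene
        motion_feats = []
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            m = np.abs(
                intensity * _shift_edge(prev_i, dr, dc)
                - prev_i * _shift_edge(intensity, dr, dc)
            )
            motion_feats.append(m)

    channels = ChannelSet(
        intensity=_channel_conspicuity([intensity], config),
        color=_channel_conspicuity([rg, by], config),
        orientation=_channel_conspicuity(orient_feats, config),
        motion=_channel_conspicuity(motion_feats, config),
        flicker=_channel_conspicuity(flick_feats, config),
    )
    final = np.mean(list(channels.as_dict().values()), axis=0)
    return final, channels


def summed_saliency_map(maps: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Element-wise sum of per-frame saliency maps."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] == 0:
        raise ValueError("need a non-empty list of 2D maps of equal shape")
    return maps.sum(axis=0)


def count_saliency_clusters(
    summed_map: np.ndarray, clamp_rel: float = 1e-6
) -> tuple[int, np.ndarray]:
    """Count connected patches of strictly positive summed saliency.

    Values below ``clamp_rel`` times the global maximum are clamped to exact
    zero first (numerical floor), then 8-connected components of the strict
    support are labelled.  Returns ``(n_clusters, labels)`` with background 0.
    """
    summed_map = np.asarray(summed_map, dtype=float)
    if summed_map.min() < 0:
        raise ValueError("summed saliency map must be non-negative")
    peak = summed_map.max()
    support = summed_map > (clamp_rel * peak if peak > 0 else 0.0)
    labels, n = ndi.label(support, structure=np.ones((3, 3), dtype=bool))
    return int(n), labels


def video_saliency(
    frames: np.ndarray, config: SaliencyConfig | None = None
) -> SaliencyVideo:
    """Per-frame saliency of a whole video plus summed map and clusters."""
    config = config or SaliencyConfig()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (T, H, W, 3) stack")
    maps = []
    prev = None
    for t in range(frames.shape[0]):
        sal, _ = frame_saliency(frames[t], prev, config)
        maps.append(sal)
        prev = frames[t]
    maps = np.asarray(maps)
    summed = summed_saliency_map(maps)
    n, labels = count_saliency_clusters(summed, config.clamp_rel)
    return SaliencyVideo(maps=maps, summed_map=summed, labels=labels, n_clusters=n)


def _hemifield_masks(width: int, geometry: ScreenGeometry) -> tuple[np.ndarray, np.ndarray]:
    x = (np.arange(width, dtype=float) - (width - 1) / 2.0) * (
        geometry.horizontal_span_deg / width
    )
    c = geometry.central_exclusion_deg
    return x < -c, x > c


def salience_lateralization_index(
    maps: np.ndarray | SaliencyVideo, geometry: ScreenGeometry | None = None
) -> HemifieldSalience:
    """Hemifield-mean saliency and ``sal_idx = (R - L) / (R + L)``.

    Per-frame means are taken over each hemifield excluding the central
    band (|x| <= ``central_exclusion_deg``), then averaged over frames.
    Positive values indicate greater salience in the right hemifield.  When
    both hemifield means are zero the index is undefined (NaN, flagged).
    """
    geometry = geometry or DEFAULT_GEOMETRY
    if isinstance(maps, SaliencyVideo):
        maps = maps.maps
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.shape[0] == 0:
        raise ValueError("need at least one saliency map")
    left_mask, right_mask = _hemifield_masks(maps.shape[2], geometry)
    if not left_mask.any() or not right_mask.any():
        raise ValueError("central exclusion band covers the whole screen")
    left = float(maps[:, :, left_mask].mean(axis=(1, 2)).mean())
    right = float(maps[:, :, right_mask].mean(axis=(1, 2)).mean())
    total = left + right
    if total <= 0.0:
        return HemifieldSalience(left=left, right=right, sal_idx=float("nan"), defined=False)
    return HemifieldSalience(
        left=left, right=right, sal_idx=(right - left) / total, defined=True
    )


def fixation_cluster_overlap(
    fixations,
    labels: np.ndarray,
    geometry: ScreenGeometry | None = None,
) -> float:
    """Percentage of fixation centroids falling inside saliency clusters.

    A fixation counts as inside a cluster iff the pixel containing its
    centroid has a positive label.  Centroids outside the screen count as
    outside any cluster.  Returns NaN for an empty fixation list.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    labels = np.asarray(labels)
    if not fixations:
        return float("nan")
    inside = 0
    for fix in fixations:
        col, row = geometry.deg_to_px(fix.centroid_x_deg, fix.centroid_y_deg)
        c, r = int(round(col)), int(round(row))
        if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1] and labels[r, c] > 0:
            inside += 1
    return 100.0 * inside / len(fixations)
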