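"""Synthetic video stimuli: moving salient events over cluttered backgrounds.

Each video is a short (default 1.5 s) colour clip containing either one
high-contrast moving event confined to one hemifield ("lat" condition,
weak competition) or one event per hemifield with asymmetric strength
("multi" condition, strong competition), over a uniform gray background
sprinkled with static low-contrast patches (clutter).  Events and patches
are Gaussian luminance/colour blobs; the analysis consumes only pixel
statistics, so no attempt is made at semantic content.

Ground truth records every planted object, the per-frame event
trajectories and an analytic salience lateralization (weight-based
hemifield asymmetry) used by the gaze generator as the planted ``sal_idx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..geometry import ScreenGeometry, DEFAULT_GEOMETRY

__all__ = [
    "VideoStimulus",
    "GroundTruth",
    "frame_counts_for_set",
    "generate_scene_layout",
    "render_video",
    "generate_video",
    "horizontal_flip",
    "mirror_truth",
]

# default clutter levels per condition (mean number of background patches)
CLUTTER_MEAN = {"lat": 6.3, "multi": 7.3}

_EVENT_COLORS = np.array(
    [
        (1.00, 0.30, 0.20),
        (0.25, 0.55, 1.00),
        (1.00, 0.85, 0.20),
        (0.35, 1.00, 0.45),
        (1.00, 0.40, 0.90),
    ]
)
_PATCH_COLOR = np.array((0.80, 0.80, 0.90))


@dataclass
class VideoStimulus:
    """Time-ordered colour frames with condition/side labels."""

    frames: np.ndarray  # (T, H, W, 3), values in [0, 1]
    fps: float
    duration_s: float
    condition: str  # 'lat' | 'multi'
    side: str  # 'left' | 'right'
    flipped: bool = False
    video_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GroundTruth:
    """Planted scene structure of one synthetic video.

    ``event_trajectories`` holds one (n_frames, 2) array of (x, y) degree
    positions per event; ``event_weights`` are the analytic salience weights
    (amplitude x sigma^2) used for ``true_lateralization``, which is the
    weight-based hemifield asymmetry (positive = rightward) that serves as
    the planted sal_idx.
    """

    condition: str
    side: str
    n_frames: int
    event_trajectories: list = field(default_factory=list)
    event_weights: list = field(default_factory=list)
    event_sigmas_deg: list = field(default_factory=list)
    event_amplitudes: list = field(default_factory=list)
    event_colors: list = field(default_factory=list)
    patch_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    patch_sigma_deg: float = 0.4
    patch_amplitude: float = 0.16
    n_background_patches: int = 0
    true_lateralization: float = 0.0


def frame_counts_for_set(
    n_videos: int, fps: float = 25.0, duration_s: float = 1.5
) -> np.ndarray:
    """Per-video frame counts whose total equals round(n * duration * fps).

    With a non-integer ``duration_s * fps`` (e.g. 1.5 s at 25 fps = 37.5)
    the counts alternate between floor and ceil (Bresenham scheme), e.g.
    140 videos of 1.5 s at 25 fps give 70 x 37 + 70 x 38 = 5250 frames.
    """
    exact = duration_s * fps
    edges = np.floor(exact * np.arange(n_videos + 1) + 0.5).astype(int)
    return np.diff(edges)


def _hemifield_box(side: str, geometry: ScreenGeometry, margin: float = 1.5):
    half_w = geometry.horizontal_span_deg / 2.0
    half_h = geometry.vertical_span_deg / 2.0
    inner = geometry.central_exclusion_deg + 1.2  # keep events clear of the band
    if side == "right":
        return (inner, half_w - margin, -half_h + margin, half_h - margin)
    return (-half_w + margin, -inner, -half_h + margin, half_h - margin)


def _event_trajectory(
    side: str, geometry: ScreenGeometry, n_frames: int, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Linear drift with reflection at the hemifield box bounds."""
    x0, x1, y0, y1 = _hemifield_box(side, geometry)
    pos = np.array([rng.uniform(x0 + 0.5, x1 - 0.5), rng.uniform(y0 + 0.5, y1 - 0.5)])
    speed = rng.uniform(1.5, 3.0)  # deg/s
    angle = rng.uniform(0, 2 * np.pi)
    vel = speed * np.array([np.cos(angle), np.sin(angle)]) / fps
    traj = np.empty((n_frames, 2))
    for t in range(n_frames):
        traj[t] = pos
        pos = pos + vel
        if pos[0] < x0 or pos[0] > x1:
            vel[0] = -vel[0]
            pos[0] = np.clip(pos[0], x0, x1)
        if pos[1] < y0 or pos[1] > y1:
            vel[1] = -vel[1]
            pos[1] = np.clip(pos[1], y0, y1)
    return traj


def generate_scene_layout(
    condition: str,
    side: str,
    clutter_mean: float | None = None,
    geometry: ScreenGeometry | None = None,
    fps: float = 25.0,
    seed: int | np.random.Generator = 0,
    duration_s: float = 1.5,
    n_frames: int | None = None,
    min_separation_deg: float = 4.5,
) -> GroundTruth:
    """Plant events and background patches without rendering any pixels.

    'lat' videos get exactly one event confined to ``side``; 'multi' videos
    get one event per hemifield with the stronger one on ``side``.  Patches
    are placed alternating between hemifields (so clutter stays roughly
    balanced), outside the central exclusion band and at least
    ``min_separation_deg`` from every other object and event trajectory
    point.  The Poisson-drawn patch count is reduced when no admissible
    position is found after bounded rejection sampling.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    if condition not in ("lat", "multi"):
        raise ValueError(f"unknown condition {condition!r}")
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if clutter_mean is None:
        clutter_mean = CLUTTER_MEAN[condition]
    if clutter_mean < 0:
        raise ValueError("clutter_mean must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_frames is None:
        n_frames = int(round(duration_s * fps))

    truth = GroundTruth(condition=condition, side=side, n_frames=n_frames)
    other = "left" if side == "right" else "right"
    if condition == "lat":
        sides = [side]
        amps = [rng.uniform(0.45, 0.65)]
        sigmas = [rng.uniform(0.40, 0.60)]
    else:
        # asymmetric event strengths: the spread of the resulting weight
        # lateralization gives the multi condition its salience variability
        strong = rng.uniform(0.50, 0.68)
        weak = rng.uniform(0.10, strong - 0.08)
        sides = [side, other]
        amps = [strong, weak]
        sigmas = [rng.uniform(0.40, 0.62), rng.uniform(0.32, 0.58)]
    for ev_side, amp, sigma in zip(sides, amps, sigmas):
        traj = _event_trajectory(ev_side, geometry, n_frames, fps, rng)
        truth.event_trajectories.append(traj)
        truth.event_sigmas_deg.append(sigma)
        truth.event_amplitudes.append(amp)
        truth.event_weights.append(amp * sigma**2)
        truth.event_colors.append(_EVENT_COLORS[rng.integers(len(_EVENT_COLORS))])

    # occupied positions: trajectory points (subsampled) + placed patches
    occupied = [traj[::4] for traj in truth.event_trajectories]
    n_patches = int(rng.poisson(clutter_mean))
    placed = []
    patch_side = rng.integers(2)  # alternate hemifields for rough balance
    half_w = geometry.horizontal_span_deg / 2.0
    half_h = geometry.vertical_span_deg / 2.0
    for k in range(n_patches):
        sign = (-1.0, 1.0)[(patch_side + k) % 2]
        for _ in range(400):
            cand = np.array(
                [sign * rng.uniform(1.8, half_w - 0.8), rng.uniform(-half_h + 0.8, half_h - 0.8)]
            )
            d2 = min(
                (np.min(np.sum((pts - cand) ** 2, axis=1)) for pts in occupied),
                default=np.inf,
            )
            if d2 >= min_separation_deg**2:
                placed.append(cand)
                occupied.append(cand[None, :])
                break
    truth.patch_positions = np.array(placed) if placed else np.zeros((0, 2))
    truth.n_background_patches = len(placed)
    truth.true_lateralization = _weight_lateralization(truth)
    if condition == "multi" and np.sign(truth.true_lateralization) != (1 if side == "right" else -1):
        # size jitter or clutter outweighed the planted event asymmetry:
        # mirror the layout so the dominant hemifield matches the side label
        truth = mirror_truth(truth)
        truth.side = side
    return truth


def _weight_lateralization(truth: GroundTruth) -> float:
    left = right = 0.0
    for traj, w in zip(truth.event_trajectories, truth.event_weights):
        mean_x = float(np.mean(traj[:, 0]))
        if mean_x >= 0:
            right += w
        else:
            left += w
    patch_w = truth.patch_amplitude * truth.patch_sigma_deg**2
    for pos in truth.patch_positions:
        if pos[0] >= 0:
            right += patch_w
        else:
            left += patch_w
    total = left + right
    return 0.0 if total == 0 else (right - left) / total


def mirror_truth(truth: GroundTruth) -> GroundTruth:
    """Mirror a layout about the vertical midline (x -> -x, side swapped)."""
    out = replace(truth)
    out.event_trajectories = [traj * np.array([-1.0, 1.0]) for traj in truth.event_trajectories]
    out.patch_positions = (
        truth.patch_positions * np.array([-1.0, 1.0])
        if len(truth.patch_positions)
        else truth.patch_positions
    )
    out.side = "left" if truth.side == "right" else "right"
    out.true_lateralization = -truth.true_lateralization
    return out


def _paint_blob(
    frame: np.ndarray,
    x_deg: float,
    y_deg: float,
    sigma_deg: float,
    amplitude: float,
    color: np.ndarray,
    geometry: ScreenGeometry,
) -> None:
    """Add a Gaussian blob in-place, restricted to a local window for speed."""
    col, row = geometry.deg_to_px(x_deg, y_deg)
    sig_px = sigma_deg / geometry.degrees_per_px
    r = int(np.ceil(4 * sig_px))
    r0, r1 = max(0, int(row) - r), min(frame.shape[0], int(row) + r + 1)
    c0, c1 = max(0, int(col) - r), min(frame.shape[1], int(col) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    g = np.exp(-((rows - row) ** 2 + (cols - col) ** 2) / (2 * sig_px**2))
    frame[r0:r1, c0:c1] += amplitude * g[..., None] * color[None, None, :]


def render_video(
    truth: GroundTruth,
    geometry: ScreenGeometry | None = None,
    fps: float = 25.0,
    duration_s: float = 1.5,
    video_id: str = "",
    background: float = 0.25,
) -> VideoStimulus:
    """Render a planted layout into colour frames (values clipped to [0, 1])."""
    geometry = geometry or DEFAULT_GEOMETRY
    n_frames = truth.n_frames
    frames = np.full(
        (n_frames, geometry.height_px, geometry.width_px, 3), background, dtype=np.float32
    )
    for t in range(n_frames):
        frame = frames[t]
        for pos in truth.patch_positions:
            _paint_blob(
                frame, pos[0], pos[1], truth.patch_sigma_deg, truth.patch_amplitude,
                _PATCH_COLOR, geometry,
            )
        for traj, sig, amp, col in zip(
            truth.event_trajectories,
            truth.event_sigmas_deg,
            truth.event_amplitudes,
            truth.event_colors,
        ):
            _paint_blob(frame, traj[t, 0], traj[t, 1], sig, amp, np.asarray(col), geometry)
    np.clip(frames, 0.0, 1.0, out=frames)
    return VideoStimulus(
        frames=frames,
        fps=fps,
        duration_s=duration_s,
        condition=truth.condition,
        side=truth.side,
        flipped=False,
        video_id=video_id,
    )


def generate_video(
    condition: str,
    side: str,
    clutter_mean: float | None = None,
    geometry: ScreenGeometry | None = None,
    fps: float = 25.0,
    seed: int = 0,
    duration_s: float = 1.5,
    n_frames: int | None = None,
    video_id: str = "",
) -> tuple[VideoStimulus, GroundTruth]:
    """Generate one synthetic video and its ground truth.

    Same seed, same arguments: bit-identical frames.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    truth = generate_scene_layout(
        condition, side, clutter_mean, geometry, fps, seed, duration_s, n_frames
    )
    video = render_video(truth, geometry, fps, duration_s, video_id)
    return video, truth


def horizontal_flip(video: VideoStimulus) -> VideoStimulus:
    """Mirror every frame about the vertical midline.

    The side label is swapped and the ``flipped`` flag toggled; applying the
    flip twice returns frames identical to the original.
    """
    return VideoStimulus(
        frames=video.frames[:, :, ::-1, :].copy(),
        fps=video.fps,
        duration_s=video.duration_s,
        condition=video.condition,
        side="left" if video.side == "right" else "right",
        flipped=not video.flipped,
        video_id=video.video_id,
    )
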