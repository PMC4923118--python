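"""Readers and writers for the package's on-disk formats.

Gaze traces are TSV (time_s, x_deg, y_deg, valid); trial tables are CSV;
videos are NPZ stacks with a JSON sidecar of labels and geometry; volumes
are NIfTI-1 via nibabel with labels in a companion CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gaze import GazeTrace
from .geometry import ScreenGeometry
from .synthetic.videos import VideoStimulus

__all__ = [
    "save_trace_tsv",
    "load_trace_tsv",
    "save_video_npz",
    "load_video_npz",
    "save_frames_png",
    "load_frames_png",
    "save_geometry_json",
    "load_geometry_json",
    "save_volume_nifti",
    "load_volume_nifti",
]


def save_trace_tsv(trace: GazeTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "x_deg": trace.x_deg,
            "y_deg": trace.y_deg,
            "valid": trace.valid.astype(int),
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# sampling_hz={trace.sampling_hz} stimulus_onset_s={trace.stimulus_onset_s} "
            f"stimulus_duration_s={trace.stimulus_duration_s}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def load_trace_tsv(path: str | Path) -> GazeTrace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    return GazeTrace(
        time_s=df["time_s"].to_numpy(),
        x_deg=df["x_deg"].to_numpy(),
        y_deg=df["y_deg"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        sampling_hz=float(meta["sampling_hz"]),
        stimulus_onset_s=float(meta["stimulus_onset_s"]),
        stimulus_duration_s=float(meta["stimulus_duration_s"]),
    )


def save_video_npz(video: VideoStimulus, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, frames=video.frames.astype(np.float32))
    sidecar = {
        "fps": video.fps,
        "duration_s": video.duration_s,
        "condition": video.condition,
        "side": video.side,
        "flipped": video.flipped,
        "video_id": video.video_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_video_npz(path: str | Path) -> VideoStimulus:
    path = Path(path)
    frames = np.load(path)["frames"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return VideoStimulus(frames=frames, **meta)


def save_frames_png(video: VideoStimulus, out_dir: str | Path) -> None:
    """Write one 8-bit PNG per frame (frame0000.png, ...) plus the sidecar."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in range(video.n_frames):
        frame8 = np.round(np.clip(video.frames[t], 0, 1) * 255).astype(np.uint8)
        iio.imwrite(out_dir / f"frame{t:04d}.png", frame8)
    sidecar = {
        "fps": video.fps,
        "duration_s": video.duration_s,
        "condition": video.condition,
        "side": video.side,
        "flipped": video.flipped,
        "video_id": video.video_id,
    }
    (out_dir / "video.json").write_text(json.dumps(sidecar, indent=1))


def load_frames_png(in_dir: str | Path) -> VideoStimulus:
    import imageio.v3 as iio

    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("frame*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame PNGs in {in_dir}")
    frames = np.stack([iio.imread(p) for p in paths]).astype(np.float32) / 255.0
    meta = json.loads((in_dir / "video.json").read_text())
    return VideoStimulus(frames=frames, **meta)


def save_geometry_json(geometry: ScreenGeometry, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "width_px": geometry.width_px,
                "height_px": geometry.height_px,
                "degrees_per_px": geometry.degrees_per_px,
                "central_exclusion_deg": geometry.central_exclusion_deg,
            },
            indent=1,
        )
    )


def load_geometry_json(path: str | Path) -> ScreenGeometry:
    return ScreenGeometry(**json.loads(Path(path).read_text()))


def save_volume_nifti(volume: np.ndarray, path: str | Path, voxel_size_mm=(3.0, 3.0, 3.75)) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_volume_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())
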