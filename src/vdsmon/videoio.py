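"""Reading and writing frame directories, sidecars and manifests.

A video on disk is a directory of zero-padded 8-bit grayscale PNGs
(``frame_000001.png`` ...) plus a ``meta.json`` sidecar holding the scene
and motion configs and the ground-truth track as (frame_index, x, y)
triples.  A dataset adds a two-column ``labels.csv`` (path, label) at its
root.  Pixel coordinates in sidecars are (x, y) = (column, row), 0-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .differencing import FrameStack
from .features import MotionTrack
from .synthetic import MotionProfile, SceneConfig, VideoSample

__all__ = [
    "write_video_dir",
    "read_frame_dir",
    "write_dataset",
    "read_manifest",
]


def write_video_dir(
    directory,
    frames: FrameStack,
    track: MotionTrack | None = None,
    scene: SceneConfig | None = None,
    profile: MotionProfile | None = None,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(len(frames)):
        iio.imwrite(directory / f"frame_{k + 1:06d}.png", frames.frames[k])
    meta = {"frame_rate": frames.frame_rate, "frame_count": len(frames)}
    if scene is not None:
        meta["scene"] = asdict(scene)
    if profile is not None:
        meta["profile"] = asdict(profile)
    if track is not None:
        meta["true_track"] = [[k, x, y] for k, x, y in track.points]
    (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return directory


def read_frame_dir(directory, frame_rate: float | None = None) -> FrameStack:
    """Load a numbered PNG/PGM directory as a FrameStack.

    The frame rate comes from ``meta.json`` when present, otherwise it
    must be passed explicitly.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"frame directory not found: {directory}")
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".png", ".pgm"))
    if not paths:
        raise FileNotFoundError(f"no .png/.pgm frames in {directory}")
    meta_path = directory / "meta.json"
    if frame_rate is None and meta_path.exists():
        frame_rate = float(json.loads(meta_path.read_text())["frame_rate"])
    if frame_rate is None:
        raise ValueError(f"no meta.json in {directory}; pass frame_rate explicitly")
    frames = np.stack([np.asarray(iio.imread(p)) for p in paths])
    if frames.ndim == 4:  # RGB(A) saved by accident: collapse to gray
        frames = frames[..., :3].mean(axis=-1)
    return FrameStack(frames, frame_rate)


def write_dataset(directory, samples: list[VideoSample], scene: SceneConfig | None = None) -> Path:
    """Write videos as video_0000/... subdirectories plus labels.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        sub = f"video_{i:04d}"
        write_video_dir(directory / sub, s.frames, s.true_track, scene)
        rows.append({"path": sub, "label": s.label})
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)
    return directory


def read_manifest(path) -> pd.DataFrame:
    """labels.csv-style manifest: columns path,label[,sex]; paths relative to it."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    if not set(df["label"].unique()) <= {+1, -1}:
        raise ValueError("manifest labels must be +1 or -1")
    df["path"] = [str((path.parent / p)) for p in df["path"]]
    return df
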