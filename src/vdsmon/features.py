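"""Centroid tracks and velocity sequences.

The detected region in each frame is collapsed to its mass center and the
target is treated as a point particle.  Between two detections the particle
covers the Euclidean distance l in time t = (frame gap) / f_w, where f_w is
the frame rate, so its speed is v = l / t in pixels per second.  The ordered
speeds form the velocity sequence that the classifier consumes.

Frames in which no region survives detection leave a *gap* in the track,
not a zero: the elapsed time of the next speed uses the true frame gap.
Speeds are unsigned; direction is not used anywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differencing import DiffConfig, FrameStack, clean_and_select, three_frame_difference

__all__ = [
    "MotionTrack",
    "VelocitySequence",
    "centroid",
    "displacement",
    "velocity_sequence",
    "track_from_frames",
]


@dataclass
class MotionTrack:
    """Per-frame centroid positions: ``(frame_index, x, y)`` triples."""

    points: list[tuple[int, float, float]]
    frame_rate: float

    def __post_init__(self) -> None:
        self.points = [(int(k), float(x), float(y)) for k, x, y in self.points]
        idx = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.points)

    def frame_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=int)

    def xy(self) -> np.ndarray:
        return np.array([[p[1], p[2]] for p in self.points], dtype=float)


@dataclass
class VelocitySequence:
    """Ordered scalar speeds (pixels/second) extracted from one video."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) and self.values.min() < 0:
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def centroid(region: np.ndarray) -> tuple[float, float]:
    """Unweighted mean ``(x, y)`` of a set of member pixels.

    ``region`` is an ``(n, 2)`` array (or iterable) of ``(x, y)`` pixel
    coordinates; the region is treated as a point particle located at its
    mass center.
    """
    pts = np.asarray(list(region) if not isinstance(region, np.ndarray) else region, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot take the centroid of an empty region")
    pts = pts.reshape(-1, 2)
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def displacement(p_a: tuple[float, float], p_b: tuple[float, float]) -> float:
    """Euclidean distance a point particle covers between two positions."""
    return math.hypot(p_b[0] - p_a[0], p_b[1] - p_a[1])


def velocity_sequence(
    track: MotionTrack,
    source_id: str = "",
    normalize_height: float | None = None,
) -> VelocitySequence:
    """Speeds between consecutive detections of a track.

    For each consecutive pair of track points the speed is
    ``displacement / elapsed_time`` with ``elapsed_time = dframe / frame_rate``
    — gap-aware, so a missed detection lengthens the time base rather than
    inflating the speed.

    ``normalize_height``, when given, divides every speed by the frame
    height, yielding heights-per-second; off by default.
    """
    if len(track) < 2:
        raise ValueError(f"a track needs >= 2 points to yield velocities, got {len(track)}")
    idx = track.frame_indices()
    xy = track.xy()
    dt = np.diff(idx) / track.frame_rate
    dl = np.hypot(*(np.diff(xy, axis=0).T))
    v = dl / dt
    if normalize_height is not None:
        v = v / float(normalize_height)
    return VelocitySequence(v, source_id=source_id)


def track_from_frames(stack: FrameStack, cfg: DiffConfig | None = None) -> MotionTrack:
    """Run three-frame differencing over a stack and collect centroids.

    Every interior frame k (1..n−2) gets a three-frame mask from frames
    (k−1, k, k+1); frames whose mask yields no surviving region are simply
    absent from the track (a gap).
    """
    cfg = cfg or DiffConfig()
    if len(stack) < 3:
        raise ValueError(f"three-frame differencing needs >= 3 frames, got {len(stack)}")
    points: list[tuple[int, float, float]] = []
    f = stack.frames
    for k in range(1, len(stack) - 1):
        mask = three_frame_difference(f[k - 1], f[k], f[k + 1], cfg, frame_index=k)
        _, region = clean_and_select(mask, cfg)
        if region is not None:
            cx, cy = centroid(region)
            points.append((k, cx, cy))
    return MotionTrack(points, stack.frame_rate)


# ---------------------------------------------------------------------------
# CSV interchange


def write_track_csv(track: MotionTrack, path) -> None:
    df = pd.DataFrame(track.points, columns=["frame_index", "x", "y"])
    df.to_csv(path, index=False)


def read_track_csv(path, frame_rate: float) -> MotionTrack:
    df = pd.read_csv(path)
    return MotionTrack(list(df[["frame_index", "x", "y"]].itertuples(index=False, name=None)), frame_rate)


def write_sequence_csv(seq: VelocitySequence, path) -> None:
    pd.DataFrame({"pair_index": np.arange(len(seq)), "speed": seq.values}).to_csv(path, index=False)


def read_sequence_csv(path, source_id: str = "") -> VelocitySequence:
    df = pd.read_csv(path)
    return VelocitySequence(df["speed"].to_numpy(), source_id=source_id or str(path))
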