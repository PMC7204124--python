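"""Moving-target detection by interframe and three-frame differencing.

Consecutive grayscale frames are subtracted pixelwise, the absolute
difference is thresholded at a preset gray-level T, and — in the
three-frame scheme — the two difference masks around a central frame are
combined with a pixelwise AND.  The AND suppresses the "image tail", the
ghost of the target's previous position that a plain two-frame difference
drags behind a moving object.  The binary mask is then cleaned with
morphological closing/opening and the largest sufficiently large connected
component is taken as the moving target.

Pixel coordinates throughout this package are ``(x, y) = (column, row)``,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "FrameStack",
    "MotionMask",
    "DiffConfig",
    "frame_difference",
    "three_frame_difference",
    "clean_and_select",
]


@dataclass
class FrameStack:
    """An ordered stack of same-shape grayscale frames with a frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with gray levels in
        ``[0, 255]``.  At least two frames (three for three-frame
        differencing).
    frame_rate
        Frames per second (the inter-frame time is its reciprocal).
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, height, width) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameStack needs at least 2 frames")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"gray levels must lie in [0, 255], found range [{lo}, {hi}]")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MotionMask:
    """Binary foreground mask attributed to one (central) frame."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")


@dataclass
class DiffConfig:
    """Differencing parameters.

    ``threshold`` is the preset gray-level T applied to the absolute frame
    difference; too large and the target is missed, too small and noise
    survives.  It may be the string ``"otsu"`` for automatic selection from
    the difference histogram.  ``morph_radius`` is the disk radius of the
    closing-then-opening cleanup (0 disables it); ``min_area`` is the
    smallest connected component, in pixels, kept as a candidate target.
    """

    threshold: float | str = 25.0
    morph_radius: int = 1
    min_area: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str):
            if self.threshold != "otsu":
                raise ValueError(f"unknown automatic threshold mode {self.threshold!r}")
        elif not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if self.morph_radius < 0:
            raise ValueError("morph_radius must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


def _resolve_threshold(diff: np.ndarray, cfg: DiffConfig) -> float:
    if cfg.threshold == "otsu":
        if diff.max() == diff.min():  # flat difference image: nothing moves
            return np.inf
        return float(threshold_otsu(diff))
    return float(cfg.threshold)


def frame_difference(
    prev: np.ndarray,
    curr: np.ndarray,
    cfg: DiffConfig | None = None,
    frame_index: int = 0,
) -> MotionMask:
    """Raw interframe difference mask: ``|curr - prev| >= T``.

    The absolute value makes gray-level changes in either direction count
    as motion.  No morphology is applied here; see :func:`clean_and_select`.
    """
    cfg = cfg or DiffConfig()
    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    diff = np.abs(curr - prev)
    t = _resolve_threshold(diff, cfg)
    return MotionMask(diff >= t, frame_index)


def three_frame_difference(
    f_prev: np.ndarray,
    f_curr: np.ndarray,
    f_next: np.ndarray,
    cfg: DiffConfig | None = None,
    frame_index: int = 0,
) -> MotionMask:
    """Three-frame difference mask: AND of the two pairwise masks.

    Thresholds ``|f_curr - f_prev|`` and ``|f_next - f_curr|`` separately
    and intersects the results.  The mask is attributed to the central
    frame, which is the position the surviving pixels describe.
    """
    r1 = frame_difference(f_prev, f_curr, cfg)
    r2 = frame_difference(f_curr, f_next, cfg)
    return MotionMask(r1.mask & r2.mask, frame_index)


def clean_and_select(
    mask: MotionMask | np.ndarray,
    cfg: DiffConfig | None = None,
) -> tuple[MotionMask, np.ndarray | None]:
    """Morphological cleanup and largest-region selection.

    Applies closing then opening with a disk of ``morph_radius`` (filling
    pinholes, then removing speckle), labels 8-connected components,
    discards those below ``min_area`` and returns the largest survivor as
    an ``(n, 2)`` array of ``(x, y)`` pixel coordinates — or ``None`` when
    nothing survives, which is a valid "no motion" outcome.

    Ties on area are broken by the smallest top-left bounding-box corner
    (row first, then column).
    """
    cfg = cfg or DiffConfig()
    if isinstance(mask, MotionMask):
        frame_index = mask.frame_index
        m = mask.mask
    else:
        frame_index = 0
        m = np.asarray(mask).astype(bool)

    if cfg.morph_radius > 0:
        selem = morphology.disk(cfg.morph_radius)
        m = morphology.closing(m, selem)
        m = morphology.opening(m, selem)

    cleaned = MotionMask(m, frame_index)
    labels = measure.label(m, connectivity=2)
    best = None
    best_key = None
    for prop in measure.regionprops(labels):
        if prop.area < cfg.min_area:
            continue
        key = (-prop.area, prop.bbox[0], prop.bbox[1])
        if best_key is None or key < best_key:
            best_key = key
            best = prop
    if best is None:
        return cleaned, None
    coords = best.coords  # (row, col)
    region = np.stack([coords[:, 1], coords[:, 0]], axis=1)  # (x, y)
    return cleaned, region
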