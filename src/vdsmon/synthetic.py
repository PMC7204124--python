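"""Synthetic laryngeal-motion videos with ground-truth tracks.

Real throat-monitoring footage of phlegm-stagnation patients is not
publicly available, so this module renders a stand-in scene: a bright
elliptical "throat marker" blob (the sticker a caregiver fixes to the
patient's throat to raise contrast) oscillating vertically on a noisy
gray background.  The two classes differ only in kinematics:

* normal swallowing/breathing — a smooth sinusoid with small positional
  jitter;
* phlegm stagnation — the same sinusoid plus Bernoulli-distributed
  high-velocity excursions ("bursts") that emulate the irregular,
  violent laryngeal movement of an obstructed airway.

None of this is clinically validated kinematics; the profiles exist to
give the detection/classification chain a controllable, reproducible
target whose difficulty (class overlap) is tunable via jitter and burst
parameters.

A detectability constraint shapes the defaults: three-frame differencing
of a *uniform* blob only fires where the central-frame blob is disjoint
from both its neighbours, which requires the per-frame displacement to
exceed the blob semi-axis along the motion.  The default marker is
therefore small (4 x 2 px semi-axes) and the default motion fast enough
(12 px amplitude at 1 Hz, 10 fps) that mid-cycle speeds exceed 2
px/frame.  Near the turning points of the sinusoid the target is
legitimately invisible to the detector and the track has gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .differencing import FrameStack
from .features import MotionTrack

__all__ = [
    "SceneConfig",
    "MotionProfile",
    "VideoSample",
    "generate_track",
    "render_frames",
    "generate_video",
    "generate_dataset",
    "default_scene",
    "separable_profiles",
    "overlapping_profiles",
]


@dataclass
class SceneConfig:
    """Rendering parameters of the synthetic scene.

    ``marker_contrast`` is the gray-level difference between the blob and
    the background, emulating the sticker (high contrast) vs no-sticker
    (low contrast) recording conditions.  ``noise_sigma`` is the standard
    deviation of additive Gaussian pixel noise in gray levels; frames are
    clipped to [0, 255] and quantized to 8 bits.
    """

    frame_count: int = 40
    height: int = 64
    width: int = 64
    frame_rate: float = 10.0
    blob_axes: tuple[float, float] = (4.0, 2.0)  # (semi_x, semi_y) pixels
    marker_contrast: float = 120.0
    noise_sigma: float = 4.0
    background_level: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 3:
            raise ValueError("frame_count must be >= 3")
        if self.marker_contrast < 0:
            raise ValueError("marker_contrast must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.blob_axes) <= 0:
            raise ValueError("blob semi-axes must be positive")


@dataclass
class MotionProfile:
    """Class-conditional kinematics of the marker.

    The vertical trajectory is ``amplitude * sin(2 pi f t)`` about the
    frame center plus per-frame Gaussian jitter; the positive (phlegm)
    class additionally receives, with probability ``burst_probability``
    per frame, a one-frame excursion of ``burst_amplitude`` pixels in a
    random direction.  ``burst_probability`` must be 0 for the negative
    class — bursts are what make the positive class positive.
    """

    class_label: int
    base_amplitude: float = 12.0
    base_frequency: float = 1.0  # cycles / second
    jitter_sigma: float = 1.0
    burst_probability: float = 0.0
    burst_amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.class_label not in (+1, -1):
            raise ValueError("class_label must be +1 or -1")
        if not 0.0 <= self.burst_probability <= 1.0:
            raise ValueError("burst_probability must lie in [0, 1]")
        if self.class_label == -1 and self.burst_probability != 0:
            raise ValueError("the negative class must have burst_probability = 0")


@dataclass
class VideoSample:
    frames: FrameStack
    label: int
    true_track: MotionTrack


def _trajectory(scene: SceneConfig, profile: MotionProfile, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(scene.frame_count)
    t = k / scene.frame_rate
    cy = scene.height / 2.0
    y = cy + profile.base_amplitude * np.sin(2 * np.pi * profile.base_frequency * t)
    if profile.jitter_sigma > 0:
        y = y + rng.normal(0.0, profile.jitter_sigma, size=scene.frame_count)
    if profile.burst_probability > 0:
        hit = rng.random(scene.frame_count) < profile.burst_probability
        sign = rng.choice([-1.0, 1.0], size=scene.frame_count)
        y = y + hit * sign * profile.burst_amplitude
    x = np.full(scene.frame_count, scene.width / 2.0)
    centers = np.stack([x, y], axis=1)

    ax, ay = scene.blob_axes
    margin = 1.0  # anti-aliased edge
    if (
        centers[:, 0].min() - ax - margin < 0
        or centers[:, 0].max() + ax + margin > scene.width - 1
        or centers[:, 1].min() - ay - margin < 0
        or centers[:, 1].max() + ay + margin > scene.height - 1
    ):
        raise ValueError(
            "trajectory leaves the frame: blob of semi-axes "
            f"{scene.blob_axes} at y in [{centers[:, 1].min():.1f}, {centers[:, 1].max():.1f}] "
            f"does not fit a {scene.width}x{scene.height} frame"
        )
    return centers


def generate_track(scene: SceneConfig, profile: MotionProfile) -> MotionTrack:
    """The scripted ground-truth trajectory, without rendering any pixels."""
    rng = np.random.default_rng(scene.seed)
    centers = _trajectory(scene, profile, rng)
    return MotionTrack([(k, c[0], c[1]) for k, c in enumerate(centers)], scene.frame_rate)


def render_frames(scene: SceneConfig, centers: np.ndarray, rng: np.random.Generator | None = None) -> FrameStack:
    """Render an anti-aliased uniform ellipse at each center.

    Pixel coverage falls linearly across a ~1 px edge band of the ellipse
    (``coverage = clip(0.5 + (1 - r) * min(ax, ay), 0, 1)`` with r the
    normalized elliptical radius), which keeps the intensity-weighted
    centroid of a noise-free frame within half a pixel of the scripted
    center.  Gaussian noise, if any, is added afterwards; output is 8-bit.
    """
    centers = np.asarray(centers, dtype=float)
    ax, ay = scene.blob_axes
    edge = min(ax, ay)
    ys = np.arange(scene.height, dtype=float)[:, None]
    xs = np.arange(scene.width, dtype=float)[None, :]
    frames = np.empty((len(centers), scene.height, scene.width), dtype=np.uint8)
    for k, (cx, cy) in enumerate(centers):
        r = np.sqrt(((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2)
        coverage = np.clip(0.5 + (1.0 - r) * edge, 0.0, 1.0)
        img = scene.background_level + scene.marker_contrast * coverage
        if scene.noise_sigma > 0:
            if rng is None:
                raise ValueError("noise_sigma > 0 requires an rng")
            img = img + rng.normal(0.0, scene.noise_sigma, img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameStack(frames, scene.frame_rate)


def generate_video(scene: SceneConfig, profile: MotionProfile) -> tuple[FrameStack, MotionTrack]:
    """One labeled video: rendered frames plus the exact generated track.

    Identical configs (including ``scene.seed``) reproduce bit-identical
    frames.  Raises if the trajectory would carry the blob out of frame.
    """
    rng = np.random.default_rng(scene.seed)
    centers = _trajectory(scene, profile, rng)
    frames = render_frames(scene, centers, rng)
    track = MotionTrack([(k, c[0], c[1]) for k, c in enumerate(centers)], scene.frame_rate)
    return frames, track


def generate_dataset(
    n_per_class: int,
    scene: SceneConfig,
    profiles: tuple[MotionProfile, MotionProfile],
    seed: int,
) -> list[VideoSample]:
    """A balanced labeled collection of synthetic videos.

    ``profiles`` is the (positive, negative) pair; each of the
    ``2 * n_per_class`` videos gets an independent child seed derived from
    ``seed``, so the whole dataset is reproducible from one integer.
    Samples alternate +1, -1.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    pos, neg = profiles
    if pos.class_label != +1 or neg.class_label != -1:
        raise ValueError("profiles must be ordered (positive, negative) with labels (+1, -1)")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class, dtype=np.uint32) % (2**31)
    samples: list[VideoSample] = []
    for i in range(n_per_class):
        for profile in (pos, neg):
            sc = SceneConfig(**{**asdict(scene), "seed": int(child_seeds[len(samples)])})
            frames, track = generate_video(sc, profile)
            samples.append(VideoSample(frames, profile.class_label, track))
    return samples


# ---------------------------------------------------------------------------
# Study-condition presets used by the evaluation scripts and tests.


def default_scene(seed: int = 0, **overrides) -> SceneConfig:
    return SceneConfig(seed=seed, **overrides)


def separable_profiles() -> tuple[MotionProfile, MotionProfile]:
    """Non-overlapping class speed distributions (easy regime).

    The positive class moves with twice the amplitude and receives
    frequent large bursts; per-video mean speeds of the two classes do
    not overlap.
    """
    pos = MotionProfile(+1, base_amplitude=16.0, base_frequency=1.0, jitter_sigma=0.3,
                        burst_probability=0.3, burst_amplitude=8.0)
    neg = MotionProfile(-1, base_amplitude=8.0, base_frequency=1.0, jitter_sigma=0.3)
    return pos, neg


def overlapping_profiles() -> tuple[MotionProfile, MotionProfile]:
    """Moderate class overlap (realistic regime).

    Both classes share the base sinusoid and jitter; only the sparse
    bursts separate them, so per-video summary statistics overlap and
    classification is genuinely imperfect.
    """
    pos = MotionProfile(+1, base_amplitude=12.0, base_frequency=1.0, jitter_sigma=1.0,
                        burst_probability=0.15, burst_amplitude=8.0)
    neg = MotionProfile(-1, base_amplitude=12.0, base_frequency=1.0, jitter_sigma=1.0)
    return pos, neg
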