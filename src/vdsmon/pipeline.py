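"""End-to-end monitoring: frames -> differencing -> velocities -> alerts.

A continuous recording is cut into overlapping windows; each window runs
three-frame differencing, centroid tracking and velocity extraction, and
the trained VDS model classifies the window's velocity sequence.  Alerts
are raised per a debouncing policy:

``any_positive``
    every positively classified window raises an alert (the literal
    "alarm starts immediately" behaviour);
``k_of_m``
    an alert is raised at a window only when at least k of the last m
    windows (including the current, which must itself be positive) were
    positive — damping single-window flips.  Defaults k=2, m=3.

Windows in which no moving region survives detection produce a
"no-motion" report entry and count as negative for the alert policy;
they never crash the pipeline.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import VDSModel, decision_value
from .differencing import DiffConfig, FrameStack
from .features import track_from_frames, velocity_sequence

__all__ = ["PipelineConfig", "AlertEvent", "run_monitor"]


@dataclass
class PipelineConfig:
    diff: DiffConfig = field(default_factory=DiffConfig)
    window_length: int = 30
    window_stride: int = 15
    alert_policy: str = "k_of_m"  # or "any_positive"
    k: int = 2
    m: int = 3

    def __post_init__(self) -> None:
        if self.window_length < 3:
            raise ValueError("window_length must be >= 3 (three-frame differencing)")
        if self.window_stride < 1:
            raise ValueError("window_stride must be >= 1")
        if self.alert_policy not in ("k_of_m", "any_positive"):
            raise ValueError(f"unknown alert_policy {self.alert_policy!r}")
        if not (1 <= self.k <= self.m):
            raise ValueError("need 1 <= k <= m")


@dataclass
class AlertEvent:
    """One raised alarm, attributed to the window that triggered it."""

    window_start_frame: int
    window_end_frame: int
    decision_value: float
    time_seconds: float  # window end frame / frame rate


def run_monitor(
    frames: FrameStack,
    model: VDSModel,
    cfg: PipelineConfig | None = None,
) -> tuple[list[AlertEvent], pd.DataFrame]:
    """Slide windows over a recording and classify each one.

    Returns the alert list and a per-window report with the frames used,
    detected-region count, sequence length, decision value and status.
    Deterministic given inputs.  Raises when the recording is shorter
    than one window.
    """
    cfg = cfg or PipelineConfig()
    n = len(frames)
    if n < cfg.window_length:
        raise ValueError(
            f"recording has {n} frames but one window needs {cfg.window_length}; "
            f"{cfg.window_length - n} more required"
        )

    alerts: list[AlertEvent] = []
    rows = []
    history: deque[bool] = deque(maxlen=cfg.m)
    for start in range(0, n - cfg.window_length + 1, cfg.window_stride):
        end = start + cfg.window_length - 1
        sub = FrameStack(frames.frames[start : end + 1], frames.frame_rate)
        track = track_from_frames(sub, cfg.diff)
        row = {
            "window_start": start,
            "window_end": end,
            "n_central_frames": cfg.window_length - 2,
            "n_detected": len(track),
        }
        if len(track) < 2:
            positive = False
            row.update(seq_length=0, decision_value=np.nan, predicted_label=0, status="no-motion")
        else:
            seq = velocity_sequence(track)
            dec = decision_value(model, seq)
            label = +1 if dec >= 0 else -1
            positive = label == +1
            row.update(seq_length=len(seq), decision_value=dec, predicted_label=label, status="ok")
        history.append(positive)

        fire = positive if cfg.alert_policy == "any_positive" else (positive and sum(history) >= cfg.k)
        if fire:
            alerts.append(
                AlertEvent(
                    window_start_frame=start,
                    window_end_frame=end,
                    decision_value=float(row["decision_value"]),
                    time_seconds=end / frames.frame_rate,
                )
            )
        row["alert"] = fire
        rows.append(row)
    return alerts, pd.DataFrame(rows)
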