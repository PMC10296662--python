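"""Streaming classification loop and virtual prosthesis actuation.

The stream is consumed in consecutive non-overlapping analysis windows
(default 2 s).  Each window runs the conditioning/feature chain, the
classifier, and a confidence gate: only predictions whose confidence is
strictly greater than the threshold (default 0.70) emit a motor command.

Class-to-command mapping: class 1 (wrist flexion) closes the gripper
(+20 deg), class 2 (fist) turns the base (+30 deg), class 3 (wrist
extension) opens the gripper (-20 deg).  Positive angles are clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from myogrip.classify import MLPModel, Prediction, forward
from myogrip.dataio import AnalysisWindow
from myogrip.features import extract

__all__ = [
    "MotorCommand",
    "ProstheticState",
    "StreamStep",
    "map_prediction",
    "apply_command",
    "stream_classify",
    "COMMAND_TABLE",
]

# class id -> (target axis, signed delta in degrees)
COMMAND_TABLE: dict[int, tuple[str, float]] = {
    1: ("gripper", +20.0),  # close
    2: ("base", +30.0),  # turn base
    3: ("gripper", -20.0),  # open
}

DEFAULT_LIMITS: dict[str, tuple[float, float]] = {
    "gripper": (0.0, 90.0),
    "base": (0.0, 180.0),
}


@dataclass(frozen=True)
class MotorCommand:
    """One actuation step: which axis, how far (signed, + = clockwise), and why."""

    target: str
    delta_angle: float
    cause: int

    def __post_init__(self) -> None:
        if self.target not in ("gripper", "base"):
            raise ValueError(f"unknown target {self.target!r}")


@dataclass(frozen=True)
class ProstheticState:
    """Virtual two-axis prosthesis pose; angles stay inside the limits."""

    gripper_angle: float = 45.0
    base_angle: float = 90.0
    limits: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_LIMITS))

    def __post_init__(self) -> None:
        for axis, angle in (("gripper", self.gripper_angle), ("base", self.base_angle)):
            lo, hi = self.limits[axis]
            if not (lo <= angle <= hi):
                raise ValueError(f"{axis} angle {angle} outside limits [{lo}, {hi}]")


@dataclass(frozen=True)
class StreamStep:
    """One decision of the streaming loop."""

    window_index: int
    prediction: Prediction
    command: MotorCommand | None
    state: ProstheticState


def map_prediction(pred: Prediction, threshold: float = 0.70) -> MotorCommand | None:
    """Gate a prediction by confidence and translate it to a motor command.

    Returns ``None`` when the confidence is not strictly greater than the
    threshold; raises for class ids outside the command table.
    """
    if pred.class_id not in COMMAND_TABLE:
        raise ValueError(f"no motor mapping for class {pred.class_id}")
    if not pred.confidence > threshold:
        return None
    target, delta = COMMAND_TABLE[pred.class_id]
    return MotorCommand(target=target, delta_angle=delta, cause=pred.class_id)


def apply_command(state: ProstheticState, cmd: MotorCommand | None) -> ProstheticState:
    """Apply a command, clamping the target angle to its limits."""
    if cmd is None:
        return state
    lo, hi = state.limits[cmd.target]
    if cmd.target == "gripper":
        angle = float(np.clip(state.gripper_angle + cmd.delta_angle, lo, hi))
        return replace(state, gripper_angle=angle)
    angle = float(np.clip(state.base_angle + cmd.delta_angle, lo, hi))
    return replace(state, base_angle=angle)


def stream_classify(
    samples: np.ndarray | Iterable,
    model: MLPModel,
    sampling_rate: float = 1000.0,
    window_duration: float = 2.0,
    hop_duration: float | None = None,
    threshold: float = 0.70,
    feature_method: str = "rms",
    envelope_ms: float = 50.0,
    subwindow_ms: float = 500.0,
    initial_state: ProstheticState | None = None,
) -> list[StreamStep]:
    """Run the full decision loop over a sample stream.

    ``samples`` is an (n_samples, n_channels) array (or any iterable of
    channel rows) at ``sampling_rate``.  Consecutive windows are featurized,
    classified, confidence-gated, and applied to the prosthesis state in
    order; a trailing partial window is discarded.  ``hop_duration``
    defaults to the window duration (non-overlapping decisions spaced
    exactly one window apart in stream time).
    """
    x = np.atleast_2d(np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                                 dtype=float))
    n_win = int(round(window_duration * sampling_rate))
    hop = n_win if hop_duration is None else int(round(hop_duration * sampling_rate))
    if hop < 1 or n_win < 1:
        raise ValueError("window and hop must span at least one sample")
    state = initial_state or ProstheticState()
    steps: list[StreamStep] = []
    index = 0
    for start in range(0, x.shape[0] - n_win + 1, hop):
        win = AnalysisWindow(
            samples=x[start : start + n_win],
            sampling_rate=sampling_rate,
            duration=window_duration,
        )
        fv = extract(win, method=feature_method, envelope_ms=envelope_ms,
                     subwindow_ms=subwindow_ms)
        if len(fv) != model.n_inputs:
            raise ValueError(
                f"stream produces {len(fv)} features per window but the model "
                f"expects {model.n_inputs} (channel-count or config mismatch)"
            )
        pred = forward(model, fv)
        cmd = map_prediction(pred, threshold=threshold)
        state = apply_command(state, cmd)
        steps.append(StreamStep(window_index=index, prediction=pred, command=cmd, state=state))
        index += 1
    return steps
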