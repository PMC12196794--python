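"""Rule-based post-fall immobility (long-lie) state machine.

After the classifier flags a fall, the monitor tracks the body
orientation — the scalar ACB angle — frame by frame. A long-lie alert is
raised when the subject has remained in the fallen state for at least
the time threshold (default 15 min) while the orientation has stayed
within the change threshold (default 15%) of its value at fall onset.
An orientation change above the threshold at any point is treated as a
recovery movement and resets the machine to "moving"; a non-fall
classification likewise resets it.

The reference orientation is fixed at fall onset and refreshed only on
reset, so slow drift accumulates rather than being rebaselined each
frame (per-frame rebaselining would let arbitrarily large cumulative
motion pass undetected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

FALL = "fall"


@dataclass
class MonitorConfig:
    longlie_time_threshold: float = 900.0  # seconds (15 min)
    orientation_change_threshold: float = 15.0  # percent
    frame_period: float = 0.1  # seconds
    epsilon_orientation: float = 1e-6  # radians, guard for the relative change

    def __post_init__(self) -> None:
        for name in ("longlie_time_threshold", "orientation_change_threshold",
                     "frame_period", "epsilon_orientation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MonitorState:
    status: str = "moving"  # moving | fall | longlie
    fall_frames: int = 0
    body_ort_old: float = math.nan  # reference ACB angle at fall onset
    longlie_detected: bool = False
    longlie_frames: int = 0  # mirrored for fidelity; reset but never read

    def fall_elapsed(self, frame_period: float) -> float:
        return self.fall_frames * frame_period


@dataclass(frozen=True)
class MonitorEvent:
    time: float  # seconds
    kind: str  # fall_start | longlie_alert | recovery | reset
    orientation_change: float = 0.0  # percent


def orientation_change(body_ort: float, body_ort_old: float,
                       epsilon: float = 1e-6) -> float:
    """Relative orientation change in percent.

    100 * |new - old| / old when the reference is at least epsilon;
    below epsilon the ratio is unstable, so the change is 0 when both
    angles are negligible and 100 otherwise.
    """
    if body_ort < 0 or body_ort_old < 0:
        raise ValueError("orientation angles must be >= 0")
    if body_ort_old < epsilon:
        return 0.0 if body_ort < epsilon else 100.0
    return 100.0 * abs(body_ort - body_ort_old) / body_ort_old


def _reset(state: MonitorState) -> None:
    state.status = "moving"
    state.fall_frames = 0
    state.longlie_frames = 0
    state.longlie_detected = False
    state.body_ort_old = math.nan


def step(state: MonitorState, classification: str, body_ort: float,
         cfg: MonitorConfig, time: float = 0.0
         ) -> tuple[MonitorState, MonitorEvent | None]:
    """Advance the state machine by one frame (state is mutated and
    returned). At most one event is emitted per step."""
    event: MonitorEvent | None = None
    if classification == FALL:
        if state.status == "moving":
            state.status = "fall"
            state.body_ort_old = body_ort
            state.fall_frames = 1
            event = MonitorEvent(time, "fall_start")
        else:
            state.fall_frames += 1
            change = orientation_change(body_ort, state.body_ort_old,
                                        cfg.epsilon_orientation)
            crossed = (state.fall_frames * cfg.frame_period
                       >= cfg.longlie_time_threshold)
            newly_detected = crossed and not state.longlie_detected
            if crossed:
                state.longlie_detected = True
                state.status = "longlie"
            if change > cfg.orientation_change_threshold:
                _reset(state)
                event = MonitorEvent(time, "recovery", change)
            elif newly_detected:
                event = MonitorEvent(time, "longlie_alert", change)
    else:
        if state.status != "moving":
            event = MonitorEvent(time, "reset")
        _reset(state)
    return state, event


def run_monitor(stream: Iterable[tuple[str, float]],
                cfg: MonitorConfig | None = None) -> list[MonitorEvent]:
    """Fold :func:`step` over an ordered (classification, ACB) stream
    starting from the moving state; returns the event log."""
    cfg = cfg or MonitorConfig()
    state = MonitorState()
    events: list[MonitorEvent] = []
    for i, (classification, body_ort) in enumerate(stream):
        _, event = step(state, classification, body_ort, cfg,
                        time=i * cfg.frame_period)
        if event is not None:
            events.append(event)
    return events
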