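"""Independent reference implementations used only by the tests.

These deliberately avoid the library's code paths: angles via explicit
vector normalization and arccos of dot products, window starts by
enumeration, and the immobility state machine as a literal, separate
transcription of the monitoring rules.
"""

from __future__ import annotations

import numpy as np


# --- geometry ---------------------------------------------------------------

def vertical_angle_oracle(upper, anchor) -> float:
    """Angle between anchor->upper and the upward vertical (0,-1)."""
    v = np.asarray(upper, dtype=float) - np.asarray(anchor, dtype=float)
    up = np.array([0.0, -1.0])
    return float(np.arccos(np.clip(v @ up / np.linalg.norm(v), -1.0, 1.0)))


def vertex_angle_oracle(a, b, c) -> float:
    """Angle at b between rays b->a and b->c."""
    u = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def whr_oracle(points) -> float:
    """Bounding-extent width/height of an (n,2) point array."""
    pts = np.asarray(points, dtype=float)
    w = pts[:, 0].max() - pts[:, 0].min()
    h = pts[:, 1].max() - pts[:, 1].min()
    return w / h


# --- windowing --------------------------------------------------------------

def window_starts_oracle(length: int, m: int, stride: int) -> list[int]:
    """All admissible stride-aligned window starts, by enumeration."""
    return [s for s in range(0, length + 1) if s % stride == 0 and s + m <= length]


# --- immobility state machine ----------------------------------------------

def monitor_oracle_step(state: tuple, classification: str, body_ort: float,
                        threshold_s: float, change_pct: float,
                        frame_period: float, eps: float
                        ) -> tuple[tuple, str | None]:
    """One step of the long-lie rules on a plain-tuple state.

    state = (status, fall_frames, reference_orientation_or_None, detected)
    """
    status, fall_frames, ref, detected = state
    event = None
    if classification == "fall":
        if status == "Moving":
            return ("Fall", 1, body_ort, False), "fall_start"
        fall_frames += 1
        if ref < eps:
            change = 0.0 if body_ort < eps else 100.0
        else:
            change = abs(body_ort - ref) / ref * 100.0
        was_detected = detected
        if fall_frames * frame_period >= threshold_s:
            detected = True
            status = "LongLie"
        if change > change_pct:
            return ("Moving", 0, None, False), "recovery"
        if detected and not was_detected:
            event = "longlie_alert"
        return (status, fall_frames, ref, detected), event
    if status != "Moving":
        event = "reset"
    return ("Moving", 0, None, False), event


def monitor_oracle_run(stream, threshold_s: float, change_pct: float,
                       frame_period: float, eps: float = 1e-6) -> list[str]:
    """Fold the oracle step over a stream; returns event kinds in order."""
    state = ("Moving", 0, None, False)
    events = []
    for classification, body_ort in stream:
        state, event = monitor_oracle_step(
            state, classification, body_ort, threshold_s, change_pct,
            frame_period, eps)
        if event is not None:
            events.append(event)
    return events
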