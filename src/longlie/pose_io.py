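"""Keypoint sequence data model, CSV/JSONL I/O, and detection-rate QC.

Coordinates follow the pose-estimator convention: normalized image
coordinates in [0, 1], origin at the top-left, y increasing *downward*.
All geometry downstream assumes this. A keypoint that the estimator
failed to localize is represented as ``None`` ("missing").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The 13 canonical keypoint names, head to foot, left before right.
CANONICAL_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "shoulder_l", "shoulder_r",
    "elbow_l", "elbow_r",
    "wrist_l", "wrist_r",
    "hip_l", "hip_r",
    "knee_l", "knee_r",
    "ankle_l", "ankle_r",
)

#: The 7 keypoints the QC analysis covers (nose, shoulders, hips, knees).
QC_KEYPOINTS: tuple[str, ...] = (
    "nose", "shoulder_l", "shoulder_r", "hip_l", "hip_r", "knee_l", "knee_r",
)


class PoseFormatError(ValueError):
    """Raised when a pose file does not match the expected dialect."""


@dataclass(frozen=True)
class Keypoint:
    """A single detected 2-D landmark.

    ``filled`` marks coordinates that were copied from an earlier frame by
    the temporal gap-filling step rather than observed directly.
    """

    x: float
    y: float
    confidence: float = 1.0
    filled: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        object.__setattr__(self, "confidence", float(self.confidence))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("keypoint coordinates must be finite")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class PoseFrame:
    """One time sample: the 13 canonical keypoints (some possibly missing)."""

    index: int
    keypoints: dict[str, Keypoint | None]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if set(self.keypoints) != set(CANONICAL_KEYPOINTS):
            missing = set(CANONICAL_KEYPOINTS) - set(self.keypoints)
            extra = set(self.keypoints) - set(CANONICAL_KEYPOINTS)
            raise ValueError(
                f"frame must carry exactly the 13 canonical keypoints; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def present(self, name: str) -> bool:
        return self.keypoints[name] is not None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseFrame):
            return NotImplemented
        return self.index == other.index and self.keypoints == other.keypoints


@dataclass
class PoseSequence:
    """An ordered keypoint time series sampled at a fixed frame period."""

    frames: list[PoseFrame]
    frame_period: float = 0.1
    label: str = "unlabeled"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if self.label not in {"fall", "adl", "unlabeled"}:
            raise ValueError(f"unknown label {self.label!r}")
        indices = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Detection-rate quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeypointRate:
    valid_frames: int
    total_frames: int
    rate: float  # percent


@dataclass
class DetectionReport:
    """Per-keypoint detection rates plus mean ± population SD (percent)."""

    per_keypoint: dict[str, KeypointRate]
    mean_rate: float
    sd_rate: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"keypoint": k, "valid_frames": r.valid_frames,
             "total_frames": r.total_frames, "rate": round(r.rate, 2)}
            for k, r in self.per_keypoint.items()
        ]
        return pd.DataFrame(rows)


def detection_rate(valid_frames: int, total_frames: int) -> float:
    """Percentage of frames in which a keypoint was validly detected."""
    if total_frames <= 0:
        raise ValueError("total_frames must be > 0")
    if not 0 <= valid_frames <= total_frames:
        raise ValueError("need 0 <= valid_frames <= total_frames")
    return 100.0 * valid_frames / total_frames


def _aggregate(counts: Mapping[str, tuple[int, int]]) -> DetectionReport:
    per = {
        name: KeypointRate(v, t, detection_rate(v, t))
        for name, (v, t) in counts.items()
    }
    rates = [r.rate for r in per.values()]
    mean = sum(rates) / len(rates)
    sd = math.sqrt(sum((r - mean) ** 2 for r in rates) / len(rates))
    return DetectionReport(per_keypoint=per, mean_rate=mean, sd_rate=sd)


def report_from_counts(counts: Mapping[str, tuple[int, int]]) -> DetectionReport:
    """Build a report directly from (valid, total) frame counts per keypoint."""
    if not counts:
        raise ValueError("counts must be non-empty")
    return _aggregate(counts)


def detection_report(
    seqs: PoseSequence | Iterable[PoseSequence],
    keypoint_subset: Sequence[str] = QC_KEYPOINTS,
    confidence_threshold: float = 0.5,
) -> DetectionReport:
    """Detection rates over one or more sequences.

    A keypoint counts as valid in a frame iff it is present with
    confidence strictly greater than ``confidence_threshold``. Counts are
    pooled across all sequences before rates are formed; the mean and
    population SD are taken over the per-keypoint rates.
    """
    if isinstance(seqs, PoseSequence):
        seqs = [seqs]
    seqs = list(seqs)
    if not keypoint_subset:
        raise ValueError("keypoint_subset must be non-empty")
    unknown = set(keypoint_subset) - set(CANONICAL_KEYPOINTS)
    if unknown:
        raise ValueError(f"unknown keypoints: {sorted(unknown)}")
    total = sum(len(s) for s in seqs)
    if total == 0:
        raise ValueError("need at least one frame")
    counts: dict[str, tuple[int, int]] = {}
    for name in keypoint_subset:
        valid = 0
        for seq in seqs:
            for frame in seq:
                kp = frame.keypoints[name]
                if kp is not None and kp.confidence > confidence_threshold:
                    valid += 1
        counts[name] = (valid, total)
    return _aggregate(counts)


# ---------------------------------------------------------------------------
# CSV / JSONL dialects
# ---------------------------------------------------------------------------

def _csv_columns() -> list[str]:
    cols = ["frame"]
    for name in CANONICAL_KEYPOINTS:
        cols += [f"{name}_x", f"{name}_y", f"{name}_conf"]
    return cols


def read_pose_csv(path: str | Path, frame_period: float = 0.1,
                  label: str = "unlabeled") -> PoseSequence:
    """Read a keypoint CSV (``frame,<name>_x,<name>_y,<name>_conf`` × 13).

    Blank cells denote missing keypoints.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    expected = _csv_columns()
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise PoseFormatError(
            f"{path}: missing required column(s) {missing_cols[:3]}"
        )
    indices = df["frame"].tolist()
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError(f"{path}: frame index not strictly increasing")
    frames = []
    for _, row in df.iterrows():
        kps: dict[str, Keypoint | None] = {}
        for name in CANONICAL_KEYPOINTS:
            x, y, c = row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_conf"]
            if pd.isna(x) or pd.isna(y):
                kps[name] = None
            else:
                kps[name] = Keypoint(float(x), float(y),
                                     1.0 if pd.isna(c) else float(c))
        idx = int(row["frame"])
        frames.append(PoseFrame(index=idx, keypoints=kps,
                                timestamp=idx * frame_period))
    return PoseSequence(frames=frames, frame_period=frame_period, label=label)


def write_pose_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence in the CSV dialect read by :func:`read_pose_csv`."""
    rows = []
    for frame in seq:
        row: dict[str, object] = {"frame": frame.index}
        for name in CANONICAL_KEYPOINTS:
            kp = frame.keypoints[name]
            if kp is None:
                row[f"{name}_x"] = row[f"{name}_y"] = row[f"{name}_conf"] = ""
            else:
                # repr of a builtin float round-trips exactly
                row[f"{name}_x"] = repr(float(kp.x))
                row[f"{name}_y"] = repr(float(kp.y))
                row[f"{name}_conf"] = repr(float(kp.confidence))
        rows.append(row)
    df = pd.DataFrame(rows, columns=_csv_columns())
    df.to_csv(path, index=False)


def write_pose_jsonl(seq: PoseSequence, path: str | Path) -> None:
    """One frame object per line: {"frame": i, "keypoints": {name: [x,y,c]}}."""
    with open(path, "w", encoding="utf-8") as fh:
        for frame in seq:
            obj = {
                "frame": frame.index,
                "keypoints": {
                    name: (None if kp is None else [kp.x, kp.y, kp.confidence])
                    for name, kp in frame.keypoints.items()
                },
            }
            fh.write(json.dumps(obj) + "\n")


def read_pose_jsonl(path: str | Path, frame_period: float = 0.1,
                    label: str = "unlabeled") -> PoseSequence:
    frames = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            kps = {}
            for name in CANONICAL_KEYPOINTS:
                val = obj["keypoints"].get(name)
                kps[name] = None if val is None else Keypoint(*val)
            idx = int(obj["frame"])
            frames.append(PoseFrame(index=idx, keypoints=kps,
                                    timestamp=idx * frame_period))
    return PoseSequence(frames=frames, frame_period=frame_period, label=label)
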