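"""Handcrafted postural geometry.

Five per-frame descriptors drive the classifier:

* WHR — width-to-height ratio of the bounding extent of the available
  shoulder and knee keypoints. Upright bodies give WHR < 1, lying
  bodies WHR > 1.
* theta1..theta3 — inclination of the lines joining the upper-body,
  whole-body and lower-body centres of gravity (COGs) relative to the
  image vertical, folded to [0, pi]: 0 means vertically aligned
  (standing), pi/2 horizontal (fallen).
* ACB — the angle at the hip centre subtended by the upper-body COG and
  the lower-body COG; near pi (180 deg) for a straight body.

All angles are two-argument-arctangent differences wrapped to (-pi, pi]
and folded by absolute value, which is numerically equivalent to the
arccos-of-normalized-dot-product formulation. The features are invariant
to translation and to isotropic scaling of the keypoints.

Coordinates are image-style (y grows downward); "above" therefore means
smaller y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_io import PoseFrame, PoseSequence, CANONICAL_KEYPOINTS

FEATURE_NAMES: tuple[str, ...] = ("whr", "theta1", "theta2", "theta3", "acb")

UPPER_BODY: tuple[str, ...] = (
    "nose", "shoulder_l", "shoulder_r", "elbow_l", "elbow_r", "wrist_l", "wrist_r",
)
LOWER_BODY: tuple[str, ...] = (
    "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
)


class FeatureUndefined(ValueError):
    """A geometric feature cannot be evaluated on this frame."""


@dataclass
class BodySegments:
    """Segment membership and optional per-keypoint mass weights.

    Weights default to uniform (the COG is then the centroid); a mass
    table may be supplied to weight keypoints unequally.
    """

    upper: tuple[str, ...] = UPPER_BODY
    lower: tuple[str, ...] = LOWER_BODY
    weights: Mapping[str, float] | None = None

    @property
    def whole(self) -> tuple[str, ...]:
        return self.upper + self.lower

    def __post_init__(self) -> None:
        if self.weights is not None and any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")


@dataclass(frozen=True)
class FrameFeatures:
    whr: float
    theta1: float
    theta2: float
    theta3: float
    acb: float

    @property
    def acb_degrees(self) -> float:
        return abs(self.acb) * 180.0 / math.pi

    @property
    def defined(self) -> bool:
        return all(math.isfinite(v) for v in self.as_tuple())

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.whr, self.theta1, self.theta2, self.theta3, self.acb)

    @classmethod
    def undefined(cls) -> "FrameFeatures":
        return cls(*([math.nan] * 5))


def _wrap_pi(angle: float) -> float:
    """Wrap to (-pi, pi]."""
    a = math.fmod(angle + math.pi, 2 * math.pi)
    if a <= 0:
        a += 2 * math.pi
    return a - math.pi


def compute_whr(frame: PoseFrame) -> float:
    """Width-to-height ratio over available shoulder and knee keypoints."""
    shoulders = [frame.keypoints[n] for n in ("shoulder_l", "shoulder_r")]
    knees = [frame.keypoints[n] for n in ("knee_l", "knee_r")]
    shoulders = [k for k in shoulders if k is not None]
    knees = [k for k in knees if k is not None]
    if not shoulders or not knees:
        raise FeatureUndefined("WHR needs at least one shoulder and one knee")
    pts = shoulders + knees
    xs = [p.x for p in pts]
    ys = [p.y for p in pts]
    w = max(xs) - min(xs)
    h = max(ys) - min(ys)
    if h == 0:
        raise FeatureUndefined("WHR undefined: zero height extent")
    return w / h


def segment_cog(frame: PoseFrame, segment: Sequence[str],
                weights: Mapping[str, float] | None = None) -> tuple[float, float]:
    """Mass-weighted mean position of a segment's available keypoints."""
    pts = [(n, frame.keypoints[n]) for n in segment if frame.keypoints[n] is not None]
    if not pts:
        raise FeatureUndefined(f"no available keypoint in segment {tuple(segment)}")
    if weights is None:
        ws = [1.0] * len(pts)
    else:
        ws = [float(weights.get(n, 1.0)) for n, _ in pts]
    total = sum(ws)
    if total <= 0:
        raise FeatureUndefined("total segment weight is zero")
    x = sum(w * kp.x for w, (_, kp) in zip(ws, pts)) / total
    y = sum(w * kp.y for w, (_, kp) in zip(ws, pts)) / total
    return (x, y)


def angle_from_vertical(upper: tuple[float, float],
                        anchor: tuple[float, float]) -> float:
    """Angle between the anchor->upper direction and the upward vertical.

    The reference is a point directly above the anchor (smaller image y),
    so a standing body scores 0 and a horizontal one pi/2. Result folded
    to [0, pi].
    """
    dx, dy = upper[0] - anchor[0], upper[1] - anchor[1]
    if dx == 0 and dy == 0:
        raise FeatureUndefined("coincident COGs: orientation undefined")
    # atan2(-1, 0) is the upward vertical reference in image coordinates
    return abs(_wrap_pi(math.atan2(dy, dx) - math.atan2(-1.0, 0.0)))


def orientation_angles(frame: PoseFrame,
                       segments: BodySegments | None = None
                       ) -> tuple[float, float, float]:
    """theta1 (upper vs whole), theta2 (upper vs lower), theta3 (whole vs lower).

    Each is the inclination of the line joining the two COGs, measured
    from the vertical through the pair's anatomically lower member.
    """
    segments = segments or BodySegments()
    cub = segment_cog(frame, segments.upper, segments.weights)
    clb = segment_cog(frame, segments.lower, segments.weights)
    cwb = segment_cog(frame, segments.whole, segments.weights)
    theta1 = angle_from_vertical(cub, cwb)
    theta2 = angle_from_vertical(cub, clb)
    theta3 = angle_from_vertical(cwb, clb)
    return (theta1, theta2, theta3)


def hip_center(frame: PoseFrame) -> tuple[float, float]:
    """Midpoint of the two hips."""
    lh, rh = frame.keypoints["hip_l"], frame.keypoints["hip_r"]
    if lh is None or rh is None:
        raise FeatureUndefined("hip centre needs both hips")
    return ((lh.x + rh.x) / 2.0, (lh.y + rh.y) / 2.0)


def acb_angle(a: tuple[float, float], b: tuple[float, float],
              c: tuple[float, float]) -> float:
    """Angle at vertex b between rays b->a and b->c, in [0, pi].

    a is the upper-body COG, b the hip centre, c the lower-body COG.
    Symmetric in a and c.
    """
    if a == b or c == b:
        raise FeatureUndefined("ACB undefined: COG coincides with hip centre")
    ang = math.atan2(c[1] - b[1], c[0] - b[0]) - math.atan2(a[1] - b[1], a[0] - b[0])
    return abs(_wrap_pi(ang))


def frame_features(frame: PoseFrame,
                   segments: BodySegments | None = None) -> FrameFeatures:
    """All five descriptors for one frame; undefined components make the
    whole frame undefined (all-NaN)."""
    segments = segments or BodySegments()
    try:
        whr = compute_whr(frame)
        t1, t2, t3 = orientation_angles(frame, segments)
        acb = acb_angle(
            segment_cog(frame, segments.upper, segments.weights),
            hip_center(frame),
            segment_cog(frame, segments.lower, segments.weights),
        )
    except FeatureUndefined:
        return FrameFeatures.undefined()
    return FrameFeatures(whr, t1, t2, t3, acb)


def features_table(seq: PoseSequence,
                   segments: BodySegments | None = None) -> pd.DataFrame:
    """Per-frame feature table with columns frame,whr,theta1,theta2,theta3,acb.

    Undefined frames appear as NaN rows.
    """
    rows = []
    for frame in seq:
        f = frame_features(frame, segments)
        rows.append({"frame": frame.index, **dict(zip(FEATURE_NAMES, f.as_tuple()))})
    return pd.DataFrame(rows, columns=["frame", *FEATURE_NAMES])


# ---------------------------------------------------------------------------
# z-score normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationModel:
    """Column means and SDs learned on the training split only."""

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...] = field(default=())


def zscore_fit(table: pd.DataFrame | np.ndarray) -> NormalizationModel:
    """Learn per-column mean/SD; rejects constant columns by name."""
    if isinstance(table, pd.DataFrame):
        cols = tuple(str(c) for c in table.columns)
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        cols = tuple(f"col{i}" for i in range(values.shape[1]))
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance feature(s): {[cols[i] for i in zero]}")
    return NormalizationModel(mean=mean, sd=sd, columns=cols)


def zscore_apply(model: NormalizationModel,
                 table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Standardize using the stored training statistics, unchanged."""
    values = (table.to_numpy(dtype=float)
              if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float))
    if values.shape[1] != model.mean.shape[0]:
        raise ValueError("column count does not match the fitted model")
    return (values - model.mean) / model.sd
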