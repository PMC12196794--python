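"""Keypoint sequence cleaning.

Three rules, applied in order:

1. confidence filter — keypoints at or below the confidence threshold
   become missing;
2. temporal gap filling — a missing required keypoint is restored by
   carrying forward its most recent *observed* value, provided the gap
   back to that observation is at most T2 frames;
3. frame elimination — frames in which a required keypoint has been
   continuously missing for more than T1 frames are removed (the whole
   run), and the sequence is re-indexed contiguously.

``clean`` iterates the cycle to a fixpoint so that removing a run cannot
leave a newly spliced run longer than T1 behind, which makes the whole
operation idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

from .pose_io import PoseFrame, PoseSequence, QC_KEYPOINTS, Keypoint


@dataclass
class CleaningConfig:
    """Thresholds for the cleaning pipeline.

    T1 (frames): a required keypoint continuously missing for more than
    T1 frames eliminates those frames. T2 (frames): gaps up to T2 are
    bridged by carrying the last observation forward. Defaults: T1 = 10
    (1 s at 10 Hz, sustained occlusion), T2 = 3 (300 ms, transient blur).
    """

    confidence_threshold: float = 0.5
    t1: int = 10
    t2: int = 3
    required_keypoints: tuple[str, ...] = QC_KEYPOINTS
    order: str = "fill_first"  # or "paper" (drop before fill)

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if not self.t1 >= self.t2 >= 1:
            raise ValueError("need T1 >= T2 >= 1")
        if self.order not in {"fill_first", "paper"}:
            raise ValueError("order must be 'fill_first' or 'paper'")


def _copy_frames(seq: PoseSequence) -> list[PoseFrame]:
    return [PoseFrame(f.index, dict(f.keypoints), f.timestamp) for f in seq]


def apply_confidence_filter(seq: PoseSequence, threshold: float = 0.5) -> PoseSequence:
    """Mark keypoints with confidence <= threshold as missing.

    The comparison is such that a keypoint survives only with confidence
    strictly greater than the threshold, matching the QC validity rule.
    Frame count is unchanged.
    """
    frames = _copy_frames(seq)
    for frame in frames:
        for name, kp in frame.keypoints.items():
            if kp is not None and kp.confidence <= threshold:
                frame.keypoints[name] = None
    return PoseSequence(frames, seq.frame_period, seq.label, dict(seq.metadata))


def fill_missing(seq: PoseSequence, t2: int = 3,
                 required: Sequence[str] = QC_KEYPOINTS) -> PoseSequence:
    """Carry the last *observed* value of a required keypoint forward.

    A missing keypoint at frame i is replaced by its value at the most
    recent frame where it was genuinely observed (not itself a filled
    copy), provided that frame is at most ``t2`` frames back. Filled
    keypoints are flagged ``filled=True``; frames before the first
    observation are untouched. Counting gaps from the last observation
    (rather than the last present value) keeps the operation idempotent
    and guarantees every filled value is a copy of a real observation.
    """
    frames = _copy_frames(seq)
    last_obs: dict[str, tuple[int, Keypoint]] = {}
    filled = 0
    for pos, frame in enumerate(frames):
        for name in required:
            kp = frame.keypoints[name]
            if kp is not None and not kp.filled:
                last_obs[name] = (pos, kp)
            elif kp is None and name in last_obs:
                obs_pos, obs_kp = last_obs[name]
                if pos - obs_pos <= t2:
                    frame.keypoints[name] = replace(obs_kp, filled=True)
                    filled += 1
    meta = dict(seq.metadata)
    meta["keypoints_filled"] = meta.get("keypoints_filled", 0) + filled
    return PoseSequence(frames, seq.frame_period, seq.label, meta)


def _reindex(frames: list[PoseFrame], frame_period: float) -> list[PoseFrame]:
    return [
        PoseFrame(i, dict(f.keypoints), i * frame_period)
        for i, f in enumerate(frames)
    ]


def drop_invalid_frames(seq: PoseSequence, t1: int = 10,
                        required: Sequence[str] = QC_KEYPOINTS) -> PoseSequence:
    """Remove frames belonging to missing runs longer than T1.

    For each required keypoint, maximal runs of consecutive missing
    frames are located; if a run is strictly longer than ``t1`` frames,
    all of its frames are removed (a run of exactly T1 is retained). The
    survivors are re-indexed contiguously and the number of removed
    frames is recorded in the sequence metadata.
    """
    n = len(seq)
    drop = [False] * n
    frames = list(seq.frames)
    for name in required:
        run_start = None
        for pos in range(n + 1):
            missing = pos < n and frames[pos].keypoints[name] is None
            if missing and run_start is None:
                run_start = pos
            elif not missing and run_start is not None:
                if pos - run_start > t1:
                    for j in range(run_start, pos):
                        drop[j] = True
                run_start = None
    kept = [f for f, d in zip(frames, drop) if not d]
    removed = n - len(kept)
    if not kept:
        warnings.warn("all frames eliminated during cleaning", stacklevel=2)
    meta = dict(seq.metadata)
    meta["frames_dropped"] = meta.get("frames_dropped", 0) + removed
    return PoseSequence(_reindex([PoseFrame(f.index, dict(f.keypoints), f.timestamp)
                                  for f in kept], seq.frame_period),
                        seq.frame_period, seq.label, meta)


def clean(seq: PoseSequence, cfg: CleaningConfig | None = None) -> PoseSequence:
    """Full cleaning pass: confidence filter, gap fill, frame elimination.

    The fill/drop cycle is repeated until the sequence stops changing,
    because eliminating a run can splice two shorter missing runs of a
    *different* keypoint into one longer than T1. The fixpoint makes
    ``clean`` idempotent. With ``order='paper'`` elimination precedes
    filling within each cycle.
    """
    cfg = cfg or CleaningConfig()
    out = apply_confidence_filter(seq, cfg.confidence_threshold)
    while True:
        before = [f.keypoints for f in out.frames]
        if cfg.order == "fill_first":
            out = fill_missing(out, cfg.t2, cfg.required_keypoints)
            out = drop_invalid_frames(out, cfg.t1, cfg.required_keypoints)
        else:
            out = drop_invalid_frames(out, cfg.t1, cfg.required_keypoints)
            out = fill_missing(out, cfg.t2, cfg.required_keypoints)
        after = [f.keypoints for f in out.frames]
        if before == after:
            break
    return out
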