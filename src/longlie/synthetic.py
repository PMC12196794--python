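"""Synthetic skeleton-trajectory generator.

Stands in for the thermal camera + pose estimator: emits 13-keypoint
sequences at 10 Hz with the statistical structure the pipeline assumes —
subject-to-subject size variation, Gaussian keypoint jitter, confidence
dropout concentrated on the knees (about 80% detection), fall
transitions that complete within 4 s, and sustained near-horizontal
posture for long-lie scenarios.

The body is a two-segment kinematic chain (trunk and legs hinged at the
hip). Its pose is described by the trunk's inclination from the image
vertical (0 = upright, pi/2 = lying) and the hip flexion ("bend")
between trunk and legs (0 = straight). This is deliberately minimal:
it drives all five postural features through their full ranges without
pretending to biomechanical fidelity.

The study protocol emulated: 10 subjects x 32 fall types and 15 ADL
types, i.e. 320 fall and 150 ADL sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pose_io import Keypoint, PoseFrame, PoseSequence

# ---------------------------------------------------------------------------
# Study participants (ages in years, heights cm, weights kg)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Participant:
    number: int
    age: int
    height_cm: int
    weight_kg: int
    sex: str


#: The ten study participants whose anthropometry the profiles emulate.
PARTICIPANTS: tuple[Participant, ...] = (
    Participant(1, 34, 150, 55, "F"),
    Participant(2, 37, 168, 75, "M"),
    Participant(3, 36, 160, 64, "M"),
    Participant(4, 30, 160, 55, "M"),
    Participant(5, 28, 168, 70, "F"),
    Participant(6, 26, 158, 49, "F"),
    Participant(7, 25, 163, 60, "F"),
    Participant(8, 24, 185, 70, "M"),
    Participant(9, 29, 158, 68, "F"),
    Participant(10, 25, 174, 68, "M"),
)


def participant_summary() -> dict[str, float]:
    """Mean and population SD of age, height and weight over the cohort."""
    ages = np.array([p.age for p in PARTICIPANTS], dtype=float)
    heights = np.array([p.height_cm for p in PARTICIPANTS], dtype=float)
    weights = np.array([p.weight_kg for p in PARTICIPANTS], dtype=float)
    return {
        "mean_age": float(ages.mean()), "sd_age": float(ages.std()),
        "mean_height": float(heights.mean()), "sd_height": float(heights.std()),
        "mean_weight": float(weights.mean()), "sd_weight": float(weights.std()),
    }


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    """Per-subject skeleton scaling (fractions of the trunk-leg span)."""

    height_scale: float = 1.0
    # levels: distance from the hip along the trunk (+) or legs (-) axis
    nose_level: float = 0.58
    shoulder_level: float = 0.45
    elbow_level: float = 0.30
    wrist_level: float = 0.16
    knee_level: float = 0.26
    ankle_level: float = 0.50
    # lateral half-widths, perpendicular to the segment axis
    shoulder_width: float = 0.11
    elbow_width: float = 0.13
    wrist_width: float = 0.12
    hip_width: float = 0.08
    knee_width: float = 0.06
    ankle_width: float = 0.05

    def __post_init__(self) -> None:
        if self.height_scale <= 0:
            raise ValueError("height_scale must be > 0")
        if not (self.nose_level > self.shoulder_level > self.elbow_level
                > self.wrist_level > 0 < self.knee_level < self.ankle_level):
            raise ValueError("levels must be ordered head-to-foot")


def default_profiles() -> list[SubjectProfile]:
    """One profile per participant, scaled by height."""
    mean_h = float(np.mean([p.height_cm for p in PARTICIPANTS]))
    return [SubjectProfile(height_scale=p.height_cm / mean_h)
            for p in PARTICIPANTS]


@dataclass(frozen=True)
class Phase:
    posture: str  # stand | walk | sit | lie | crawl
    duration: float  # seconds
    transition: str = "none"  # none | fall_forward | fall_backward | fall_side | fall_collapse
    transition_duration: float = 1.0
    end_bend: float = 0.10  # hip flexion of the post-fall pose (straight vs curled)

    _POSTURES = ("stand", "walk", "sit", "lie", "crawl")
    _TRANSITIONS = ("none", "fall_forward", "fall_backward", "fall_side",
                    "fall_collapse")

    def __post_init__(self) -> None:
        if self.posture not in self._POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        if self.transition not in self._TRANSITIONS:
            raise ValueError(f"unknown transition {self.transition!r}")
        if self.duration <= 0 or self.transition_duration <= 0:
            raise ValueError("durations must be > 0")
        if self.transition != "none" and self.transition_duration > 4.0:
            raise ValueError("fall transitions must complete within 4 s")


@dataclass
class ActivityScript:
    name: str
    phases: list[Phase]

    @property
    def is_fall(self) -> bool:
        return any(p.transition != "none" for p in self.phases)


@dataclass
class GeneratorConfig:
    n_subjects: int = 10
    n_fall_types: int = 32
    n_adl_types: int = 15
    frame_period: float = 0.1
    keypoint_noise_sd: float = 0.005
    knee_dropout_prob: float = 0.2
    other_dropout_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.knee_dropout_prob, self.other_dropout_prob):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout probabilities must be in [0, 1)")
        if min(self.n_subjects, self.n_fall_types, self.n_adl_types) < 1:
            raise ValueError("counts must be >= 1")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")


# ---------------------------------------------------------------------------
# Skeleton construction
# ---------------------------------------------------------------------------

def _direction(phi: float) -> tuple[float, float]:
    """Unit vector at inclination phi from the upward image vertical."""
    return (math.sin(phi), -math.cos(phi))


def _perp(phi: float) -> tuple[float, float]:
    return (math.cos(phi), math.sin(phi))


def make_skeleton(body_axis_angle: float, bend_angle: float,
                  center: tuple[float, float] = (0.5, 0.5),
                  profile: SubjectProfile | None = None,
                  index: int = 0, frame_period: float = 0.1) -> PoseFrame:
    """Place the 13 keypoints for a trunk/legs pose.

    ``body_axis_angle`` is the trunk's inclination from vertical (0 =
    upright, pi/2 = lying); ``bend_angle`` the hip flexion (0 =
    straight). ``center`` is the hip centre in normalized image
    coordinates. All confidences are 1.0 (degradation is applied by the
    activity simulator).
    """
    p = profile or SubjectProfile()
    h = 0.35 * p.height_scale  # trunk-leg span in normalized units
    a = body_axis_angle
    legs = a + math.pi - bend_angle
    ua, pa = _direction(a), _perp(a)
    ul, pl = _direction(legs), _perp(legs)
    cx, cy = center

    def at(level: float, width: float, seg_dir, seg_perp, side: int
           ) -> tuple[float, float]:
        return (cx + level * h * seg_dir[0] + side * width * h * seg_perp[0],
                cy + level * h * seg_dir[1] + side * width * h * seg_perp[1])

    pts = {
        "nose": at(p.nose_level, 0.0, ua, pa, 0),
        "shoulder_l": at(p.shoulder_level, p.shoulder_width, ua, pa, -1),
        "shoulder_r": at(p.shoulder_level, p.shoulder_width, ua, pa, +1),
        "elbow_l": at(p.elbow_level, p.elbow_width, ua, pa, -1),
        "elbow_r": at(p.elbow_level, p.elbow_width, ua, pa, +1),
        "wrist_l": at(p.wrist_level, p.wrist_width, ua, pa, -1),
        "wrist_r": at(p.wrist_level, p.wrist_width, ua, pa, +1),
        "hip_l": at(0.0, p.hip_width, ua, pa, -1),
        "hip_r": at(0.0, p.hip_width, ua, pa, +1),
        "knee_l": at(p.knee_level, p.knee_width, ul, pl, -1),
        "knee_r": at(p.knee_level, p.knee_width, ul, pl, +1),
        "ankle_l": at(p.ankle_level, p.ankle_width, ul, pl, -1),
        "ankle_r": at(p.ankle_level, p.ankle_width, ul, pl, +1),
    }
    kps = {name: Keypoint(x, y, 1.0) for name, (x, y) in pts.items()}
    return PoseFrame(index=index, keypoints=kps, timestamp=index * frame_period)


# ---------------------------------------------------------------------------
# Pose tracks: per-frame (axis, bend, cx, cy)
# ---------------------------------------------------------------------------

# posture targets: axis (rad), bend (rad), hip-centre height cy
_POSTURE_TARGETS = {
    "stand": (0.00, 0.05, 0.42),
    "walk": (0.08, 0.15, 0.42),
    "sit": (0.15, 1.35, 0.55),
    "lie": (math.pi / 2, 0.08, 0.62),
    "crawl": (1.35, 1.00, 0.58),
}

# a deliberate lie-down or sit-down eases much more slowly than a fall
_EASE_TIME = {"stand": 1.0, "walk": 1.0, "sit": 2.0, "lie": 5.0, "crawl": 1.5}

_FALL_DX = {"fall_forward": 0.16, "fall_backward": -0.16,
            "fall_side": 0.07, "fall_collapse": 0.0}


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _build_track(script: ActivityScript, frame_period: float
                 ) -> tuple[np.ndarray, dict]:
    """Per-frame (axis, bend, cx, cy) plus ground-truth timing info."""
    segments: list[np.ndarray] = []
    state = np.array([*_POSTURE_TARGETS[script.phases[0].posture][:2],
                      0.5, _POSTURE_TARGETS[script.phases[0].posture][2]])
    t_cursor = 0.0
    truth: dict = {"fall_window": None, "axis_change": 0.0,
                   "fall_transition": None}
    walk_x = 0.0

    def _tri(d):
        # bounce the drift inside +-0.15 around the sequence centre
        return 0.15 - np.abs((d + 0.15) % 0.6 - 0.3)

    after_fall = False
    for phase in script.phases:
        n = max(1, round(phase.duration / frame_period))
        axis_t, bend_t, cy_t = _POSTURE_TARGETS[phase.posture]
        if after_fall and phase.posture == "lie":
            # hold the post-impact pose instead of sweeping back upright
            axis_t, bend_t, cy_t = state[0], state[1], state[3]
        ease = min(_EASE_TIME[phase.posture], phase.duration / 2.0)
        n_ease = max(1, round(ease / frame_period))
        t = np.arange(n) * frame_period
        s = _smoothstep(np.arange(n) / n_ease)
        axis = state[0] + (axis_t - state[0]) * s
        bend = state[1] + (bend_t - state[1]) * s
        cy = state[3] + (cy_t - state[3]) * s
        cx = np.full(n, state[2])
        if phase.posture in ("walk", "crawl"):
            speed = 0.030 if phase.posture == "walk" else 0.015
            drift = walk_x + speed * t
            cx = cx + _tri(drift) - _tri(walk_x)
            walk_x = float(drift[-1])
            if phase.posture == "walk":
                axis = axis + 0.03 * np.sin(2 * math.pi * t / 0.9)
                cy = cy + 0.004 * np.sin(2 * math.pi * t / 0.45)
                bend = bend + 0.05 * np.abs(np.sin(2 * math.pi * t / 0.9))
            else:
                bend = bend + 0.08 * np.sin(2 * math.pi * t / 1.2)
        segments.append(np.column_stack([axis, bend, cx, cy]))
        state = segments[-1][-1].copy()
        t_cursor += n * frame_period
        after_fall = after_fall and phase.transition == "none"
        if phase.transition != "none":
            after_fall = True
            n_tr = max(2, round(phase.transition_duration / frame_period))
            s = _smoothstep(np.arange(1, n_tr + 1) / n_tr)
            sign = -1.0 if phase.transition == "fall_backward" else 1.0
            axis_end = sign * (math.pi / 2) * 1.02
            bend_end = phase.end_bend
            cx_end = state[2] + _FALL_DX[phase.transition]
            cy_end = 0.62
            seg = np.column_stack([
                state[0] + (axis_end - state[0]) * s,
                state[1] + (bend_end - state[1]) * s,
                state[2] + (cx_end - state[2]) * s,
                state[3] + (cy_end - state[3]) * s,
            ])
            segments.append(seg)
            truth["fall_window"] = (t_cursor, t_cursor + n_tr * frame_period)
            truth["fall_transition"] = phase.transition
            truth["axis_change"] = abs(axis_end - state[0])
            state = seg[-1].copy()
            t_cursor += n_tr * frame_period
    return np.vstack(segments), truth


def _degrade(track: np.ndarray, profile: SubjectProfile,
             cfg: GeneratorConfig, rng: np.random.Generator
             ) -> list[PoseFrame]:
    frames = []
    for i, (axis, bend, cx, cy) in enumerate(track):
        frame = make_skeleton(axis, bend, (cx, cy), profile, index=i,
                              frame_period=cfg.frame_period)
        kps = {}
        for name, kp in frame.keypoints.items():
            x = kp.x + rng.normal(0.0, cfg.keypoint_noise_sd)
            y = kp.y + rng.normal(0.0, cfg.keypoint_noise_sd)
            p_drop = (cfg.knee_dropout_prob if name.startswith("knee")
                      else cfg.other_dropout_prob)
            if rng.random() < p_drop:
                conf = rng.uniform(0.0, 0.5)  # sub-threshold, not removed:
                # the confidence filter is exercised downstream
            else:
                conf = rng.uniform(0.75, 1.0)
            kps[name] = Keypoint(x, y, conf)
        frames.append(PoseFrame(index=i, keypoints=kps,
                                timestamp=i * cfg.frame_period))
    return frames


def simulate_activity(script: ActivityScript, profile: SubjectProfile,
                      cfg: GeneratorConfig, seed: int) -> PoseSequence:
    """Simulate one recording of a scripted activity.

    Deterministic given ``seed``. The label is "fall" iff the script
    contains a fall transition. Ground-truth fall timing is stored in
    the sequence metadata (``fall_window``, ``axis_change``).
    """
    rng = np.random.default_rng(seed)
    track, truth = _build_track(script, cfg.frame_period)
    frames = _degrade(track, profile, cfg, rng)
    meta = {"activity": script.name, "seed": seed, **truth}
    meta.pop("_end_bend", None)
    return PoseSequence(frames=frames, frame_period=cfg.frame_period,
                        label="fall" if script.is_fall else "adl",
                        metadata=meta)


# ---------------------------------------------------------------------------
# Study protocol
# ---------------------------------------------------------------------------

def fall_scripts(n_types: int = 32) -> list[ActivityScript]:
    """Deterministic enumeration of fall variants.

    Variants cross fall direction (4) x pre-fall activity (stand/walk) x
    fall speed (fast/slow) x end pose (straight/curled), cycling if more
    types are requested. Pre-fall and post-fall lying phases are kept
    under 4 s so every analysis window overlaps the fall transition.
    """
    directions = ("fall_forward", "fall_backward", "fall_side", "fall_collapse")
    scripts = []
    for i in range(n_types):
        direction = directions[i % 4]
        pre = ("stand", "walk")[(i // 4) % 2]
        speed = (0.7, 1.3)[(i // 8) % 2]
        end_bend = (0.10, 0.55)[(i // 16) % 2]
        pre_dur = 2.5 + 0.25 * (i % 5)
        post = 2.5 + 0.2 * ((i * 3) % 5)
        phases = [
            Phase(pre, pre_dur, transition=direction,
                  transition_duration=speed, end_bend=end_bend),
            Phase("lie", post),
        ]
        scripts.append(ActivityScript(
            name=f"fall_{i:02d}_{direction}_{pre}", phases=phases))
    return scripts


def adl_scripts(n_types: int = 15) -> list[ActivityScript]:
    """Deterministic catalogue of activities of daily living."""
    catalogue = [
        ("stand", [("stand", 12.0)]),
        ("walk", [("walk", 12.0)]),
        ("stand_walk_stand", [("stand", 4.0), ("walk", 5.0), ("stand", 4.0)]),
        ("sit_down", [("stand", 3.0), ("sit", 8.0)]),
        ("sit", [("sit", 12.0)]),
        ("sit_stand", [("stand", 3.0), ("sit", 5.0), ("stand", 4.0)]),
        ("lie_down", [("stand", 3.0), ("lie", 9.0)]),
        ("get_up", [("lie", 8.0), ("stand", 5.0)]),
        ("walk_sit", [("walk", 5.0), ("sit", 7.0)]),
        ("crawl", [("crawl", 12.0)]),
        ("walk_crawl", [("walk", 4.0), ("crawl", 8.0)]),
        ("sit_lie", [("sit", 4.0), ("lie", 8.0)]),
        ("walk_lie", [("walk", 4.0), ("lie", 8.0)]),
        ("crawl_stand", [("stand", 3.0), ("crawl", 5.0), ("stand", 4.0)]),
        ("walk_sit_lie", [("walk", 4.0), ("sit", 4.0), ("lie", 6.0)]),
    ]
    scripts = []
    for i in range(n_types):
        name, phases = catalogue[i % len(catalogue)]
        scripts.append(ActivityScript(
            name=f"adl_{i:02d}_{name}",
            phases=[Phase(p, d) for p, d in phases]))
    return scripts


def generate_study(cfg: GeneratorConfig | None = None) -> list[PoseSequence]:
    """Emulate the full study: every subject performs every activity type.

    With defaults this yields 10 x 32 = 320 fall sequences and
    10 x 15 = 150 ADL sequences. Per-sequence seeds derive from
    ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    profiles = default_profiles()
    falls = fall_scripts(cfg.n_fall_types)
    adls = adl_scripts(cfg.n_adl_types)
    n_total = cfg.n_subjects * (len(falls) + len(adls))
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=n_total)
    sequences = []
    idx = 0
    for s in range(cfg.n_subjects):
        profile = profiles[s % len(profiles)]
        for script in falls + adls:
            seq = simulate_activity(script, profile, cfg, int(seeds[idx]))
            seq.metadata["subject"] = s + 1
            seq.metadata["id"] = f"s{s + 1:02d}_{script.name}"
            sequences.append(seq)
            idx += 1
    return sequences


# ---------------------------------------------------------------------------
# Long-lie scenarios
# ---------------------------------------------------------------------------

def generate_longlie_scenario(pre_fall: float = 20.0,
                              lie_duration: float = 960.0,
                              orientation_jitter: float = 5.0,
                              recovery: bool = False,
                              recovery_time: float = 600.0,
                              cfg: GeneratorConfig | None = None,
                              seed: int = 7) -> tuple[PoseSequence, dict]:
    """A scripted post-fall immobility recording plus its ground truth.

    The subject stands for ``pre_fall`` seconds, falls within 1 s, then
    lies for ``lie_duration`` seconds while the ACB angle wobbles within
    ``orientation_jitter`` percent of its post-fall value. With
    ``recovery`` set, a repositioning movement (ACB change of about 20%,
    above the 15% stability threshold) starts ``recovery_time`` seconds
    after the fall completes.

    Returns the degraded sequence and a truth dict with the per-frame
    classification stream ("adl" before the fall begins, "fall" after),
    the fall onset time, and the recovery window if scripted.
    """
    cfg = cfg or GeneratorConfig()
    if min(pre_fall, lie_duration) <= 0:
        raise ValueError("durations must be > 0")
    fp = cfg.frame_period
    fall_dur = 1.0
    n_pre = round(pre_fall / fp)
    n_fall = round(fall_dur / fp)
    n_lie = round(lie_duration / fp)

    axis0, bend0, cy0 = _POSTURE_TARGETS["stand"]
    axis1, bend1, cy1 = math.pi / 2 * 1.02, 0.08, 0.62
    acb0 = math.pi - bend1  # ACB after the fall, approx

    t_lie = np.arange(n_lie) * fp
    # scripted wobble uses half the jitter budget; keypoint noise uses the rest
    amp = 0.5 * (orientation_jitter / 100.0) * acb0
    wobble = amp * np.sin(2 * math.pi * t_lie / 15.0)
    bend_lie = bend1 + wobble
    if recovery:
        ease = _smoothstep((t_lie - recovery_time) / 2.0)
        bend_rec = bend1 + 0.20 * acb0  # ~20% ACB change, > 15% threshold
        # the subject settles after repositioning: wobble fades with the move
        bend_lie = bend1 + wobble * (1.0 - 0.8 * ease) + (bend_rec - bend1) * ease

    track = np.vstack([
        np.column_stack([np.full(n_pre, axis0), np.full(n_pre, bend0),
                         np.full(n_pre, 0.45), np.full(n_pre, cy0)]),
        np.column_stack([
            axis0 + (axis1 - axis0) * _smoothstep(np.arange(1, n_fall + 1) / n_fall),
            bend0 + (bend1 - bend0) * _smoothstep(np.arange(1, n_fall + 1) / n_fall),
            0.45 + 0.16 * _smoothstep(np.arange(1, n_fall + 1) / n_fall),
            cy0 + (cy1 - cy0) * _smoothstep(np.arange(1, n_fall + 1) / n_fall),
        ]),
        np.column_stack([np.full(n_lie, axis1), bend_lie,
                         np.full(n_lie, 0.61), np.full(n_lie, cy1)]),
    ])
    rng = np.random.default_rng(seed)
    profile = default_profiles()[0]
    frames = _degrade(track, profile, cfg, rng)
    fall_start = n_pre * fp
    classifications = ["adl"] * n_pre + ["fall"] * (n_fall + n_lie)
    truth = {
        "fall_start_time": fall_start,
        "fall_end_time": fall_start + fall_dur,
        "classifications": classifications,
        "recovery_window": ((fall_start + fall_dur + recovery_time,
                             fall_start + fall_dur + recovery_time + 2.0)
                            if recovery else None),
    }
    seq = PoseSequence(frames=frames, frame_period=fp, label="fall",
                       metadata={"activity": "longlie_scenario", "seed": seed})
    return seq, truth
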