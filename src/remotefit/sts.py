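"""30-second sit-to-stand (30s-STS) repetition counter.

Input is a per-frame stream of 2-D skeleton keypoints in the 17-joint COCO
layout (produced upstream by any pose-estimation model; image coordinates,
y increasing downward).  Knee (hip-knee-ankle) and hip (shoulder-hip-knee)
joint angles drive a three-way posture classifier (sitting / standing /
transition), a debounced state machine turns the per-frame labels into
completed sit-to-stand events, and an arms-crossed check (both wrists held
near the chest, i.e. close to the shoulder midpoint) decides whether each
repetition counts as correct.  The score is the number of correct
repetitions whose onset lies inside the 30-s window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .config import StsConfig
from .exceptions import InvalidInputError, UndefinedStatisticError, UnusableSequenceError

COCO_JOINTS: tuple[str, ...] = (
    "nose",
    "left_eye", "right_eye",
    "left_ear", "right_ear",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError("keypoint confidence must be in [0, 1]")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class PoseFrame:
    """One video frame: timestamp plus all 17 named keypoints.

    Joints the extractor missed are present with confidence 0.
    """

    t: float
    keypoints: dict[str, Keypoint]

    def __post_init__(self) -> None:
        missing = set(COCO_JOINTS) - set(self.keypoints)
        for name in missing:
            self.keypoints[name] = Keypoint(0.0, 0.0, 0.0)

    def __getitem__(self, joint: str) -> Keypoint:
        return self.keypoints[joint]


@dataclass
class PoseSequence:
    frames: list[PoseFrame]
    fps: Optional[float] = None

    def __post_init__(self) -> None:
        ts = [f.t for f in self.frames]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise InvalidInputError("frame timestamps must be nondecreasing")

    def __len__(self) -> int:
        return len(self.frames)


class PostureLabel(Enum):
    SITTING = "sitting"
    STANDING = "standing"
    TRANSITION = "transition"
    UNKNOWN = "unknown"


@dataclass
class RepEvent:
    t_start: float
    t_end: float
    correct: bool
    reason: str = "ok"


@dataclass
class StsResult:
    correct_count: int
    incorrect_count: int
    events: list[RepEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "correct": self.correct_count,
            "incorrect": self.incorrect_count,
            "events": [
                {"t_start": e.t_start, "t_end": e.t_end, "correct": e.correct, "reason": e.reason}
                for e in self.events
            ],
        }


def joint_angle(
    p_proximal: tuple[float, float],
    p_vertex: tuple[float, float],
    p_distal: tuple[float, float],
) -> float:
    """Interior angle at the vertex, in degrees, in [0, 180].

    Invariant to rotation, translation and uniform scaling of the three
    points; undefined (raises) when either limb vector is zero.
    """
    v1 = (p_proximal[0] - p_vertex[0], p_proximal[1] - p_vertex[1])
    v2 = (p_distal[0] - p_vertex[0], p_distal[1] - p_vertex[1])
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if not all(map(math.isfinite, (*v1, *v2))):
        raise InvalidInputError("non-finite point in joint angle")
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedStatisticError("joint angle undefined for coincident points")
    c = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


_SIDE_JOINTS = {
    "left": ("left_shoulder", "left_hip", "left_knee", "left_ankle"),
    "right": ("right_shoulder", "right_hip", "right_knee", "right_ankle"),
}


def _side_angles(frame: PoseFrame, side: str, min_conf: float) -> Optional[tuple[float, float]]:
    """(knee_angle, hip_angle) for one body side, or None if any required
    joint is below the confidence threshold."""
    shoulder, hip, knee, ankle = (frame[j] for j in _SIDE_JOINTS[side])
    if any(k.confidence < min_conf for k in (shoulder, hip, knee, ankle)):
        return None
    try:
        knee_angle = joint_angle(hip.xy, knee.xy, ankle.xy)
        hip_angle = joint_angle(shoulder.xy, hip.xy, knee.xy)
    except UndefinedStatisticError:
        return None
    return knee_angle, hip_angle


def classify_posture(frame: PoseFrame, config: Optional[StsConfig] = None) -> PostureLabel:
    """Sitting / standing / transition from knee and hip angles.

    Angles are averaged over the body sides whose shoulder, hip, knee and
    ankle all pass the confidence threshold (single-side fallback covers
    profile camera views).  Standing requires both angles at or above the
    standing threshold, sitting both at or below the sitting threshold;
    anything else is a transition.  UNKNOWN when no side is usable.
    """
    cfg = config or StsConfig()
    sides = [a for s in ("left", "right") if (a := _side_angles(frame, s, cfg.keypoint_confidence))]
    if not sides:
        return PostureLabel.UNKNOWN
    knee = sum(a[0] for a in sides) / len(sides)
    hip = sum(a[1] for a in sides) / len(sides)
    if knee >= cfg.standing_angle and hip >= cfg.standing_angle:
        return PostureLabel.STANDING
    if knee <= cfg.sitting_angle and hip <= cfg.sitting_angle:
        return PostureLabel.SITTING
    return PostureLabel.TRANSITION


def arm_position_ok(frame: PoseFrame, config: Optional[StsConfig] = None) -> bool:
    """True iff both wrists lie within ``arm_radius_frac`` of the shoulder
    breadth from the shoulder midpoint (a chest proxy for arms crossed at
    the wrists and held against the chest).  A low-confidence wrist or
    shoulder fails the check."""
    cfg = config or StsConfig()
    ls, rs = frame["left_shoulder"], frame["right_shoulder"]
    lw, rw = frame["left_wrist"], frame["right_wrist"]
    if any(k.confidence < cfg.keypoint_confidence for k in (ls, rs, lw, rw)):
        return False
    breadth = math.hypot(ls.x - rs.x, ls.y - rs.y)
    if breadth == 0.0:
        return False
    mid = ((ls.x + rs.x) / 2.0, (ls.y + rs.y) / 2.0)
    radius = cfg.arm_radius_frac * breadth
    return all(math.hypot(w.x - mid[0], w.y - mid[1]) <= radius for w in (lw, rw))


def full_body_visibility_check(
    frame: PoseFrame,
    frame_size: tuple[float, float],
    config: Optional[StsConfig] = None,
) -> bool:
    """Head-to-toe framing check: the head (nose or either eye) and both
    ankles must be confident and inside the image with a 2% border margin."""
    cfg = config or StsConfig()
    w, h = frame_size
    mx, my = cfg.visibility_margin * w, cfg.visibility_margin * h

    def inside(k: Keypoint) -> bool:
        return (
            k.confidence >= cfg.keypoint_confidence
            and mx <= k.x <= w - mx
            and my <= k.y <= h - my
        )

    head_ok = any(inside(frame[j]) for j in ("nose", "left_eye", "right_eye"))
    return head_ok and inside(frame["left_ankle"]) and inside(frame["right_ankle"])


_ORDINAL = {PostureLabel.SITTING: 0, PostureLabel.TRANSITION: 1, PostureLabel.STANDING: 2}
_FROM_ORDINAL = {v: k for k, v in _ORDINAL.items()}


def _median_filter_labels(
    labelled: list[tuple[float, PostureLabel]], debounce_s: float
) -> list[tuple[float, PostureLabel]]:
    """Temporal median filter on the ordinal posture labels.

    Sitting < transition < standing is an ordered scale, so a short median
    filter (about one debounce interval wide) removes single-frame flickers
    caused by keypoint noise near an angle threshold without shifting the
    timing of genuine state changes.
    """
    if len(labelled) < 3:
        return labelled
    ts = np.array([t for t, _ in labelled])
    dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 0.0
    if dt <= 0:
        return labelled
    half = max(1, int(round(debounce_s / (2.0 * dt))))
    codes = np.array([_ORDINAL[lab] for _, lab in labelled])
    smooth = codes.copy()
    for i in range(codes.size):
        lo, hi = max(0, i - half), min(codes.size, i + half + 1)
        smooth[i] = int(np.median(codes[lo:hi]))
    return [(t, _FROM_ORDINAL[c]) for (t, _), c in zip(labelled, smooth)]


def _debounced_states(
    labelled: list[tuple[float, PostureLabel]], debounce_s: float
) -> list[tuple[PostureLabel, float]]:
    """Collapse per-frame labels into committed states.

    A state commits once it has persisted ``debounce_s`` seconds; shorter
    flickers never register.  Returns (state, entry_time) pairs; the entry
    time is the first frame of the committed run.
    """
    committed: list[tuple[PostureLabel, float]] = []
    current: Optional[PostureLabel] = None
    cand: Optional[PostureLabel] = None
    cand_t0 = 0.0
    for t, lab in labelled:
        if lab == current:
            cand = None
            continue
        if cand is None or lab != cand:
            cand, cand_t0 = lab, t
        if t - cand_t0 >= debounce_s:
            committed.append((cand, cand_t0))
            current = cand
            cand = None
    return committed


def count_reps(
    seq: PoseSequence,
    window: Optional[float] = None,
    config: Optional[StsConfig] = None,
) -> StsResult:
    """Count correct and incorrect sit-to-stand repetitions.

    A repetition is one completed sitting -> transition -> standing pass of
    the debounced state machine; it is credited at the frame standing is
    (re)entered and scored only if its onset (the moment the sitter leaves
    the chair) lies inside the scoring window.  It is correct when the
    arms-crossed check holds on at least ``arm_hold_frac`` of its
    transition frames; a transition that sinks back to sitting without
    reaching standing is an incorrect repetition (incomplete extension).
    """
    cfg = config or StsConfig()
    win = cfg.window_s if window is None else window
    per_frame = [(f.t, classify_posture(f, cfg), arm_position_ok(f, cfg)) for f in seq.frames]
    labelled = [(t, lab) for t, lab, _ in per_frame if lab is not PostureLabel.UNKNOWN]
    if not labelled:
        raise UnusableSequenceError("no frame yields a usable posture")
    t0 = seq.frames[0].t
    labelled = _median_filter_labels(labelled, cfg.debounce_s)
    committed = _debounced_states(labelled, cfg.debounce_s)

    def arm_fraction(ts: float, te: float) -> float:
        trans = [ok for t, lab, ok in per_frame if ts <= t <= te and lab is PostureLabel.TRANSITION]
        if not trans:  # very low fps: judge on every frame in the span
            trans = [ok for t, _, ok in per_frame if ts <= t <= te]
        return sum(trans) / len(trans) if trans else 0.0

    events: list[RepEvent] = []
    # the protocol starts with the subject seated (pre-test countdown), so
    # the initial condition is read from the first frame, not debounced
    seated = labelled[0][1] is PostureLabel.SITTING
    in_attempt = False
    attempt_start = 0.0
    for state, t in committed:
        if state is PostureLabel.SITTING:
            if in_attempt:
                events.append(RepEvent(attempt_start, t, False, "incomplete-extension"))
                in_attempt = False
            seated = True
        elif state is PostureLabel.TRANSITION:
            if seated and not in_attempt:
                in_attempt = True
                attempt_start = t
            seated = False
        elif state is PostureLabel.STANDING:
            if not in_attempt and seated:
                # transition too brief to commit: date the attempt from the
                # last sitting-labelled frame before standing was entered
                sit_ts = [ft for ft, lab in labelled if lab is PostureLabel.SITTING and ft < t]
                in_attempt = True
                attempt_start = sit_ts[-1] if sit_ts else t
            if in_attempt:
                ok = arm_fraction(attempt_start, t) >= cfg.arm_hold_frac
                events.append(RepEvent(attempt_start, t, ok, "ok" if ok else "arms-not-crossed"))
                in_attempt = False
            seated = False

    scored = [e for e in events if t0 <= e.t_start < t0 + win]
    correct = sum(1 for e in scored if e.correct)
    return StsResult(correct, len(scored) - correct, scored)
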