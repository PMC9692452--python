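"""Body-segment joint angles and their RULA scores.

Every segment score is a base score from the printed worksheet band of its
position angle plus named +1 adjustments, capped at the segment's RULA
range (upper arm 1-6, lower arm 1-3, neck 1-6, trunk 1-6, legs 1-2).  The
position formulas are chain angles over body-joint tokens; all bands are
lower-inclusive / upper-exclusive except where the worksheet prints a
strict ">".

Sign conventions.  The worksheet distinguishes flexion from extension for
the upper arm and the neck, which an unsigned chain angle cannot express.
The sign is taken from the projection of the distal joint onto the
anterior normal of the frontal (coronal) plane, estimated from the two
hips and the neck: ``n = (j05 - j02) x (j06 - j02)`` points anterior for a
y-forward, right-hip-first skeleton.  The convention is config-overridable
via the registry.

The legs score is fixed: the assessment protocol has every subject working
standing with legs and feet unsupported, which the worksheet scores 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    normal_vector,
    three_point_angle,
    vector_angle,
)
from .skeleton import BodyFrame

__all__ = [
    "SegmentScore",
    "anterior_normal",
    "upper_arm_base",
    "lower_arm_base",
    "neck_base",
    "trunk_base",
    "upper_arm_angle",
    "lower_arm_angle",
    "neck_angle",
    "trunk_position",
    "upper_arm_score",
    "lower_arm_score",
    "neck_score",
    "trunk_score",
    "legs_score",
]

#: |angle| below this reads as the worksheet's exact "0 deg" band (degrees);
#: shared with the wrist neutral band.
DEFAULT_NEUTRAL_BAND = 1.0

_ARM_TOKENS = {
    # side: (position a,b,c), (raise a,b,c), (abduction a,b,c),
    #       (lower a,b,c), (across-midline a,b,c)
    "right": (("08", "07", "05"), ("04", "02", "07"), ("02", "07", "08"),
              ("09", "08", "07"), ("07", "03", "09")),
    "left": (("11", "10", "06"), ("04", "19", "02"), ("02", "10", "11"),
             ("12", "11", "10"), ("10", "03", "12")),
}

_SEGMENT_CAP = {"upper_arm": 6, "lower_arm": 3, "neck": 6, "trunk": 6,
                "legs": 2}


@dataclass(frozen=True)
class SegmentScore:
    """Score of one body segment: base band plus named +1 adjustments."""

    segment: str
    side: str               # left / right / center
    score: int
    base: int
    components: dict[str, int] = field(default_factory=dict)
    angle: float = float("nan")   # raw (signed where applicable) position angle


def _capped(segment: str, side: str, base: int, components: dict[str, int],
            angle: float) -> SegmentScore:
    total = min(base + sum(components.values()), _SEGMENT_CAP[segment])
    return SegmentScore(segment, side, total, base, components, angle)


def _chain(frame: BodyFrame, tokens) -> float | None:
    pts = [frame.joint(t) for t in tokens]
    if any(p is None for p in pts):
        return None
    try:
        return three_point_angle(*pts)
    except DegenerateGeometryError:
        return None


def anterior_normal(frame: BodyFrame) -> np.ndarray | None:
    """Anterior-pointing normal of the frontal plane through neck and hips."""
    j02, j05, j06 = (frame.joint(t) for t in ("02", "05", "06"))
    if j02 is None or j05 is None or j06 is None:
        return None
    try:
        n = normal_vector(j02, j05, j06)
    except DegenerateGeometryError:
        return None
    return n / np.linalg.norm(n)


def _sagittal_sign(frame: BodyFrame, distal: str, proximal: str) -> float:
    """+1 when the distal joint lies anterior of the proximal one."""
    n = anterior_normal(frame)
    d, p = frame.joint(distal), frame.joint(proximal)
    if n is None or d is None or p is None:
        return 1.0
    return 1.0 if float(np.dot(d - p, n)) >= 0.0 else -1.0


# ---------------------------------------------------------------------------
# printed band mappings (pure functions of the raw angle)

def upper_arm_base(angle: float) -> int:
    """+1 (-20,20), +2 (-inf,-20), +2 (20,45), +3 (45,90), +4 (90,inf)."""
    if -20.0 <= angle < 20.0:
        return 1
    if angle < -20.0 or angle < 45.0:
        return 2
    if angle < 90.0:
        return 3
    return 4


def lower_arm_base(angle: float) -> int:
    """+1 (60,100), +2 (0,60), +2 (100,inf)."""
    return 1 if 60.0 <= angle < 100.0 else 2


def neck_base(angle: float) -> int:
    """+1 (0,10), +2 (10,20), +3 (20,inf), +4 (-inf,0) (extension)."""
    if angle < 0.0:
        return 4
    if angle < 10.0:
        return 1
    if angle < 20.0:
        return 2
    return 3


def trunk_base(position: float,
               neutral_band: float = DEFAULT_NEUTRAL_BAND) -> int:
    """+1 (0 deg), +2 (0,20), +3 (20,60), +4 (60,inf)."""
    if abs(position) < neutral_band:
        return 1
    if position < 20.0:
        return 2
    if position < 60.0:
        return 3
    return 4


# ---------------------------------------------------------------------------
# raw angles

def upper_arm_angle(frame: BodyFrame, side: str) -> float | None:
    """Signed upper-arm position angle (elbow anterior => positive)."""
    pos_t, *_ = _ARM_TOKENS[side]
    raw = _chain(frame, pos_t)
    if raw is None:
        return None
    return raw * _sagittal_sign(frame, pos_t[0], pos_t[1])


def lower_arm_angle(frame: BodyFrame, side: str) -> float | None:
    return _chain(frame, _ARM_TOKENS[side][3])


def neck_angle(frame: BodyFrame) -> float | None:
    """Signed neck position angle (head anterior => positive flexion)."""
    raw = _chain(frame, ("01", "02", "04"))
    if raw is None:
        return None
    return raw * _sagittal_sign(frame, "01", "02")


def trunk_position(frame: BodyFrame) -> float | None:
    """180 minus the angle between the head->waist segment and vertical."""
    j01, j04 = frame.joint("01"), frame.joint("04")
    if j01 is None or j04 is None:
        return None
    vertical = np.asarray(frame.registry.vertical_axis, dtype=float)
    try:
        return 180.0 - vector_angle(j04 - j01, vertical)
    except DegenerateGeometryError:
        return None


# ---------------------------------------------------------------------------
# segment scores

def upper_arm_score(frame: BodyFrame, side: str) -> SegmentScore | None:
    """Base band of the signed position angle, +1 shoulder raised (>90),
    +1 abducted (>20); capped at 6."""
    _, raise_t, abd_t, *_ = _ARM_TOKENS[side]
    angle = upper_arm_angle(frame, side)
    raise_a = _chain(frame, raise_t)
    abd_a = _chain(frame, abd_t)
    if angle is None or raise_a is None or abd_a is None:
        return None
    components = {
        "shoulder_raised": 1 if raise_a > 90.0 else 0,
        "abducted": 1 if abd_a > 20.0 else 0,
    }
    return _capped("upper_arm", side, upper_arm_base(angle), components, angle)


def lower_arm_score(frame: BodyFrame, side: str) -> SegmentScore | None:
    """Base band of the elbow angle, +1 working across the midline (>90),
    +1 out to the side of the body (>30); capped at 3."""
    pos_t, _, _, _, across_t = _ARM_TOKENS[side]
    angle = lower_arm_angle(frame, side)
    across_a = _chain(frame, across_t)
    out_a = _chain(frame, pos_t)  # printed formula coincides with upper arm
    if angle is None or across_a is None or out_a is None:
        return None
    components = {
        "across_midline": 1 if across_a > 90.0 else 0,
        "out_to_side": 1 if out_a > 30.0 else 0,
    }
    return _capped("lower_arm", side, lower_arm_base(angle), components, angle)


def neck_score(frame: BodyFrame) -> SegmentScore | None:
    """Base band of the signed neck angle, +1 side bending (|90 - chain
    angle over left shoulder, neck, head| > 20).  Neck twist is excluded
    from the protocol."""
    angle = neck_angle(frame)
    bend_raw = _chain(frame, ("10", "02", "01"))
    if angle is None or bend_raw is None:
        return None
    bend = 90.0 - bend_raw
    components = {"side_bending": 1 if abs(bend) > 20.0 else 0}
    return _capped("neck", "center", neck_base(angle), components, angle)


def trunk_score(frame: BodyFrame,
                neutral_band: float = DEFAULT_NEUTRAL_BAND
                ) -> SegmentScore | None:
    """Base band of the trunk position, +1 twisted, +1 side bending.

    The twist formula mixes the left-hip->waist segment with the frontal
    plane normal through (neck, hips); the neutral upright skeleton reads
    90 deg there, so the twist metric is the departure from 90.  Side
    bending fires when either printed hip chain angle exceeds 20 deg.
    """
    position = trunk_position(frame)
    j02, j04, j05, j06 = (frame.joint(t) for t in ("02", "04", "05", "06"))
    if position is None or any(
        j is None for j in (j02, j04, j05, j06)
    ):
        return None
    try:
        nv = normal_vector(j02, j05, j06)
        twist = abs(90.0 - vector_angle(j04 - j06, nv))
        side_r = three_point_angle(j02, j04, j05)
        side_l = three_point_angle(j02, j04, j06)
    except DegenerateGeometryError:
        return None
    components = {
        "twisted": 1 if twist > 20.0 else 0,
        "side_bending": 1 if (side_r > 20.0 or side_l > 20.0) else 0,
    }
    return _capped("trunk", "center", trunk_base(position, neutral_band),
                   components, position)


def legs_score(standing_unsupported: bool = True) -> SegmentScore:
    """2 when standing with legs/feet unsupported (the study protocol),
    1 when legs and feet are supported and balanced."""
    score = 2 if standing_unsupported else 1
    return SegmentScore("legs", "center", score, score, {}, float("nan"))
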