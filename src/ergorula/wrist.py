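"""Wrist kinematics from hand-tracking joints and their RULA scores.

Four quantities are measured per hand from five finger joints:

* **flexion-extension** - angle between the middle-finger proximal-phalanx
  endpoint (x13) and metacarpal endpoint (x14).  In the default ``literal``
  mode both joints are taken as position vectors from the configured origin
  (the sensor origin), exactly as the two-vector cosine formula reads; the
  ``recentered`` mode first translates both points so a wrist-reference
  joint becomes the origin, which makes the angle origin-independent.  The
  sign (up = extension, down = flexion) comes from the component of x13
  along the calibration palm normal.
* **radial-ulnar deviation** - unsigned departure of the chain angle
  (x05, x04, x24) from its value at calibration.  The raw chain angle of a
  neutral wrist is not zero, so deviation is measured against the
  calibration pose to make the 15 deg worksheet threshold meaningful.
* **pronation-supination** - angle between the current palm-plane normal
  (through x13, x04, x24) and the calibration ("initial position",
  handshake) normal.
* the end-of-range adjustment reuses the same plane-normal angle; the score
  switches band at 105 deg.

Scores follow the printed wrist rows of the worksheet: position 1-3 by
flexion-extension band plus 1 for a >=15 deg deviation (capped at 4); twist
1 in mid-range, 2 past 105 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    normal_vector,
    plane_angle,
    three_point_angle,
    vector_angle,
)
from .skeleton import HandFrame, Stream, ValidationError

__all__ = [
    "CalibrationError",
    "SideCalibration",
    "CalibrationPose",
    "WristAngles",
    "WristScore",
    "calibrate",
    "flexion_extension",
    "radial_ulnar",
    "pronation_supination",
    "wrist_angles",
    "wrist_position_score",
    "wrist_twist_score",
]

SIDES = ("left", "right")

#: |flexion-extension| below this reads as the neutral 0-deg band (degrees).
DEFAULT_NEUTRAL_BAND = 1.0

#: deviation >= this adds 1 to the wrist position score (degrees).
DEVIATION_THRESHOLD = 15.0

#: plane-normal angle above this scores wrist twist 2 (degrees).
TWIST_THRESHOLD = 105.0


class CalibrationError(ValidationError):
    """No usable calibration frame for a hand side."""


@dataclass(frozen=True)
class SideCalibration:
    normal: np.ndarray       # palm-plane normal at the initial position
    neutral_ru: float        # chain angle (x05, x04, x24) at calibration, deg
    frame_index: int


@dataclass(frozen=True)
class CalibrationPose:
    """Per-side initial (neutral handshake) hand pose reference."""

    sides: dict[str, SideCalibration] = field(default_factory=dict)

    def __getitem__(self, side: str) -> SideCalibration:
        return self.sides[side]


_CAL_ROLES = ("middle_pp_end", "thumb_mc_end", "pinky_mc_end",
              "index_dp_start")


def _palm_points(frame: HandFrame, side: str):
    x13 = frame.role(side, "middle_pp_end")
    x04 = frame.role(side, "thumb_mc_end")
    x24 = frame.role(side, "pinky_mc_end")
    return x13, x04, x24


def calibrate(hand_stream: Stream, policy: str | int = "first_valid"
              ) -> CalibrationPose:
    """Capture per-side palm normals and neutral deviation angles.

    ``policy`` selects the calibration frame: ``"first_valid"`` (default)
    uses, per side, the first frame in which all four scoring joints are
    present; an integer pins a specific frame index for both sides.
    """
    sides: dict[str, SideCalibration] = {}
    for side in SIDES:
        indices = (
            [int(policy)] if not isinstance(policy, str)
            else range(len(hand_stream))
        )
        for i in indices:
            frame = hand_stream.frame(i)
            joints = [frame.role(side, r) for r in _CAL_ROLES]
            if any(j is None for j in joints):
                continue
            x13, x04, x24 = _palm_points(frame, side)
            x05 = frame.role(side, "index_dp_start")
            try:
                normal = normal_vector(x13, x04, x24)
                neutral_ru = three_point_angle(x05, x04, x24)
            except DegenerateGeometryError:
                continue
            sides[side] = SideCalibration(normal, neutral_ru, i)
            break
        if side not in sides:
            raise CalibrationError(
                f"no valid calibration frame for the {side} hand"
            )
    return CalibrationPose(sides)


def flexion_extension(frame: HandFrame, side: str,
                      calibration: CalibrationPose,
                      mode: str = "literal",
                      origin=(0.0, 0.0, 0.0),
                      wrist_ref: str = "00") -> float | None:
    """Signed flexion-extension angle in degrees (positive = up/extension).

    Returns None when a required joint is missing (frame unscorable).
    """
    x13 = frame.role(side, "middle_pp_end")
    x14 = frame.role(side, "middle_mc_end")
    if x13 is None or x14 is None:
        return None
    origin = np.asarray(origin, dtype=float)
    if mode == "literal":
        a, b = x13 - origin, x14 - origin
    elif mode == "recentered":
        ref = frame.joint(side, wrist_ref)
        if ref is None:
            return None
        a, b = x13 - ref, x14 - ref
    else:
        raise ValueError(f"unknown flexion-extension mode {mode!r}")
    try:
        mag = vector_angle(a, b)
    except DegenerateGeometryError:
        return None
    sign = 1.0 if float(np.dot(a, calibration[side].normal)) >= 0.0 else -1.0
    return sign * mag


def radial_ulnar(frame: HandFrame, side: str,
                 calibration: CalibrationPose) -> float | None:
    """Unsigned radial-ulnar deviation from the calibration pose, degrees."""
    x05 = frame.role(side, "index_dp_start")
    x04 = frame.role(side, "thumb_mc_end")
    x24 = frame.role(side, "pinky_mc_end")
    if x05 is None or x04 is None or x24 is None:
        return None
    try:
        raw = three_point_angle(x05, x04, x24)
    except DegenerateGeometryError:
        return None
    return abs(raw - calibration[side].neutral_ru)


def pronation_supination(frame: HandFrame, side: str,
                         calibration: CalibrationPose) -> float | None:
    """Angle between current and calibration palm-plane normals, [0, 180]."""
    x13, x04, x24 = _palm_points(frame, side)
    if x13 is None or x04 is None or x24 is None:
        return None
    try:
        current = normal_vector(x13, x04, x24)
        return plane_angle(current, calibration[side].normal)
    except DegenerateGeometryError:
        return None


@dataclass(frozen=True)
class WristAngles:
    """The three wrist kinematic quantities for one side."""

    flexion_extension: float   # signed, positive = up/extension
    radial_ulnar: float        # unsigned deviation from the neutral pose
    pronation_supination: float  # [0, 180] vs the calibration plane
    side: str


def wrist_angles(frame: HandFrame, side: str, calibration: CalibrationPose,
                 mode: str = "literal", origin=(0.0, 0.0, 0.0),
                 wrist_ref: str = "00") -> WristAngles | None:
    """All three wrist angles, or None when the frame is unscorable."""
    fe = flexion_extension(frame, side, calibration, mode, origin, wrist_ref)
    ru = radial_ulnar(frame, side, calibration)
    ps = pronation_supination(frame, side, calibration)
    if fe is None or ru is None or ps is None:
        return None
    return WristAngles(fe, ru, ps, side)


@dataclass(frozen=True)
class WristScore:
    position_score: int  # 1..4
    twist_score: int     # 1..2
    side: str


def wrist_position_score(fe: float, ru: float,
                         neutral_band: float = DEFAULT_NEUTRAL_BAND) -> int:
    """Wrist position score 1-4 from signed flexion-extension and deviation.

    Base 1 inside the neutral band, 2 up to 15 deg either way, 3 beyond;
    +1 when the radial-ulnar deviation reaches 15 deg; capped at 4.
    """
    afe = abs(fe)
    if afe < neutral_band:
        base = 1
    elif afe <= 15.0:
        base = 2
    else:
        base = 3
    adj = 1 if ru >= DEVIATION_THRESHOLD else 0
    return min(base + adj, 4)


def wrist_twist_score(ps: float) -> int:
    """Wrist twist score: 1 in mid-range, 2 past the 105 deg band edge."""
    if not 0.0 <= ps <= 180.0:
        raise ValueError(f"pronation-supination angle {ps} outside [0, 180]")
    return 2 if ps > TWIST_THRESHOLD else 1


def score_wrist(angles: WristAngles,
                neutral_band: float = DEFAULT_NEUTRAL_BAND) -> WristScore:
    return WristScore(
        position_score=wrist_position_score(
            angles.flexion_extension, angles.radial_ulnar, neutral_band
        ),
        twist_score=wrist_twist_score(angles.pronation_supination),
        side=angles.side,
    )
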