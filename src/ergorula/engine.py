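"""RULA scoring engine: section scores, grand scores and risk levels.

Section A covers the arm and wrist (upper arm, lower arm, wrist position,
wrist twist); section B covers neck, trunk and legs.  Arm segments are
scored from the body stream and wrist segments from the hand stream, so
the section-A score fuses both sensors.  Three grand scores are produced
per frame: left (A from the left side + B), right (A from the right side
+ B), and general, where the per-component maximum of the left and right
section-A inputs is looked up ("Max score") before combining with B.
Applying the maximum per component, upstream of the table-A lookup,
guarantees the general grand score dominates both sided ones because every
table is monotone.

Muscle-use and force/load inputs exist in the interfaces but default to 0:
the assessment protocol this package implements excludes them (as it does
the neck-twist adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from . import body as _body
from . import wrist as _wrist
from .preprocess import FusedFrame
from .rula_tables import TABLE_A, TABLE_B, TABLE_C
from .wrist import CalibrationPose

__all__ = [
    "score_A",
    "score_B",
    "grand_score",
    "risk_level",
    "RulaResult",
    "score_frame",
    "score_frames",
]

RISK_LEVELS = ("negligible", "low", "medium", "high")


def _check(name: str, value: int, hi: int) -> int:
    value = int(value)
    if not 1 <= value <= hi:
        raise ValueError(f"{name} score {value} outside 1..{hi}")
    return value


def score_A(upper_arm: int, lower_arm: int, wrist_position: int,
            wrist_twist: int, muscle: int = 0, force: int = 0) -> int:
    """Section-A posture score from table A (plus muscle/force, default 0)."""
    u = _check("upper arm", upper_arm, 6)
    l = _check("lower arm", lower_arm, 3)
    w = _check("wrist position", wrist_position, 4)
    t = _check("wrist twist", wrist_twist, 2)
    return int(TABLE_A[u - 1, l - 1, w - 1, t - 1]) + muscle + force


def score_B(neck: int, trunk: int, legs: int, muscle: int = 0,
            force: int = 0) -> int:
    """Section-B posture score from table B (plus muscle/force, default 0)."""
    n = _check("neck", neck, 6)
    t = _check("trunk", trunk, 6)
    g = _check("legs", legs, 2)
    return int(TABLE_B[n - 1, t - 1, g - 1]) + muscle + force


def grand_score(A: int, B: int) -> int:
    """Grand score 1-7 from table C; inputs capped at the table edges."""
    if A < 1 or B < 1:
        raise ValueError("section scores must be >= 1")
    return int(TABLE_C[min(A, 8) - 1, min(B, 7) - 1])


def risk_level(grand: int) -> str:
    """Risk level of a grand score: 1-2 negligible, 3-4 low, 5-6 medium,
    7 high."""
    if not 1 <= grand <= 7:
        raise ValueError(f"grand score {grand} outside 1..7")
    if grand <= 2:
        return "negligible"
    if grand <= 4:
        return "low"
    if grand <= 6:
        return "medium"
    return "high"


@dataclass(frozen=True)
class RulaResult:
    """Per-frame RULA outcome: segment scores, section scores, grand scores
    and risk levels for left / right / general."""

    timestamp: float
    segments: Mapping[str, int]   # keys like "upper_arm_left", "neck", ...
    A_left: int
    A_right: int
    A_max: int
    B: int
    grand_left: int
    grand_right: int
    grand_general: int
    risk_left: str
    risk_right: str
    risk_general: str
    activity: str = ""

    def as_row(self) -> dict:
        row = {"timestamp": self.timestamp}
        row.update(self.segments)
        row.update(
            A_left=self.A_left, A_right=self.A_right, A_max=self.A_max,
            B=self.B, grand_left=self.grand_left,
            grand_right=self.grand_right, grand_general=self.grand_general,
            risk_left=self.risk_left, risk_right=self.risk_right,
            risk_general=self.risk_general,
        )
        return row


def score_frame(fused: FusedFrame, calibration: CalibrationPose,
                neutral_band: float = 1.0,
                fe_mode: str = "literal",
                standing_unsupported: bool = True) -> RulaResult | None:
    """Score one fused frame; returns None when any segment is unscorable.

    Arm scores come from the body payload, wrist scores from the hand
    payload; B is computed once; the general grand score uses per-component
    left/right maxima ahead of the table-A lookup.
    """
    seg: dict[str, int] = {}
    sided: dict[str, dict[str, int]] = {"left": {}, "right": {}}
    for side in ("left", "right"):
        ua = _body.upper_arm_score(fused.body, side)
        la = _body.lower_arm_score(fused.body, side)
        wa = _wrist.wrist_angles(fused.hands, side, calibration, fe_mode)
        if ua is None or la is None or wa is None:
            return None
        ws = _wrist.score_wrist(wa, neutral_band)
        sided[side] = {
            "upper_arm": ua.score, "lower_arm": la.score,
            "wrist_position": ws.position_score,
            "wrist_twist": ws.twist_score,
        }
        seg[f"upper_arm_{side}"] = ua.score
        seg[f"lower_arm_{side}"] = la.score
        seg[f"wrist_position_{side}"] = ws.position_score
        seg[f"wrist_twist_{side}"] = ws.twist_score
    neck = _body.neck_score(fused.body)
    trunk = _body.trunk_score(fused.body, neutral_band)
    if neck is None or trunk is None:
        return None
    legs = _body.legs_score(standing_unsupported)
    seg["neck"], seg["trunk"], seg["legs"] = neck.score, trunk.score, legs.score

    A_left = score_A(**sided["left"])
    A_right = score_A(**sided["right"])
    A_max = score_A(**{
        k: max(sided["left"][k], sided["right"][k]) for k in sided["left"]
    })
    B = score_B(neck.score, trunk.score, legs.score)
    g_l, g_r, g_g = (grand_score(a, B) for a in (A_left, A_right, A_max))
    return RulaResult(
        timestamp=fused.timestamp,
        segments=seg,
        A_left=A_left, A_right=A_right, A_max=A_max, B=B,
        grand_left=g_l, grand_right=g_r, grand_general=g_g,
        risk_left=risk_level(g_l), risk_right=risk_level(g_r),
        risk_general=risk_level(g_g),
        activity=fused.label.high if fused.label else "",
    )


def score_frames(fused_frames, calibration: CalibrationPose,
                 **kwargs) -> list[RulaResult]:
    """Score a fused sequence, silently skipping unscorable frames."""
    results = []
    for f in fused_frames:
        r = score_frame(f, calibration, **kwargs)
        if r is not None:
            results.append(r)
    return results
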