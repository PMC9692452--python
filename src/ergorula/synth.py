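"""Synthetic body- and hand-stream generator with known ground truth.

The generator inverts the scoring geometry: given target values for the
posture formulas (the angles the scorer will measure), it places skeleton
joints so that every *targeted* formula evaluates to its target within
1e-6 degrees, then replicates the pose into timestamped frames at the two
sensor rates (body 30 Hz, hands 64 Hz), optionally adding angular jitter,
random joint dropouts and three-level activity labels.  All randomness
flows from a single seed.

Hand poses decouple: the palm triangle, the middle-finger pair and the
index joint control pronation-supination, flexion-extension and
radial-ulnar deviation independently, so the hand is constructed in
closed form from a flat template.  Body poses do not decouple - the
printed formulas share joints across segments (the lower-arm out-to-side
formula *is* the upper-arm position formula; the neck side-bending
formula involves the left shoulder) - so body joints are solved jointly:
18 free direction parameters (trunk tilt, head, torso, hip twist, both
shoulder/elbow/wrist directions) against the targeted formula residuals,
by damped least squares from a canonical neutral init.  A target left as
``None`` is unconstrained; the achieved value is reported in the ground
truth either way.  Infeasible target combinations raise
:class:`FeasibilityError` naming the worst residuals - some printed
combinations are geometrically impossible (e.g. a small left upper-arm
position angle together with an inactive left abduction angle), which is
a property of the formulas, not of the solver.

Limb lengths are fixed arbitrary constants: every scored quantity is an
angle, so scale cancels.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from . import body as _body
from . import wrist as _wrist
from .engine import grand_score, risk_level, score_A, score_B
from .geometry import (
    normal_vector,
    rotation_matrix,
    three_point_angle,
    tilt_towards,
    vector_angle,
)
from .io import write_body_stream, write_hand_stream, write_labels
from .preprocess import FusedFrame
from .skeleton import (
    DEFAULT_BODY_REGISTRY,
    DEFAULT_HAND_REGISTRY,
    ActivityLabel,
    BodyFrame,
    HandFrame,
    Stream,
)

__all__ = [
    "FeasibilityError",
    "ArmTargets",
    "WristTargets",
    "PostureSpec",
    "SessionSpec",
    "solve_body_pose",
    "solve_hand_pose",
    "make_posture_frames",
    "make_session",
    "make_expert_file",
    "achieved_angles",
    "true_scores",
]

TOL_DEG = 1e-6


class FeasibilityError(ValueError):
    """The targeted formula values cannot be realised simultaneously."""


# ---------------------------------------------------------------------------
# target specifications


@dataclass(frozen=True)
class ArmTargets:
    """Target formula angles for one arm (None = unconstrained)."""

    position: float | None = 10.0        # signed upper-arm position angle
    shoulder_raise: float | None = None  # raise-adjustment chain angle
    abduction: float | None = None       # abduction-adjustment chain angle
    elbow: float | None = 80.0           # lower-arm position chain angle
    across_midline: float | None = None  # across-midline chain angle


@dataclass(frozen=True)
class WristTargets:
    """Target wrist kinematics for one hand, relative to the neutral
    template (which doubles as the calibration pose).

    Flexion-extension is realised by lifting the middle proximal-phalanx
    endpoint out of the palm plane, and that same joint defines the palm
    plane the pronation-supination measure uses, so a non-zero
    flexion-extension necessarily tilts the measured palm normal.  A
    ``pronation_supination`` of None (the default) leaves the palm
    orientation at whatever the flexion-extension target implies; an
    explicit value is realised exactly when the combination is
    geometrically consistent and raises :class:`FeasibilityError`
    otherwise."""

    flexion_extension: float = 0.0    # signed, positive = up/extension
    radial_ulnar: float = 0.0         # deviation from neutral, >= 0
    pronation_supination: float | None = None  # palm-normal angle, [0,180]


#: Right-arm neutral: feasible jointly with the torso defaults (a small
#: position angle forces the elbow direction close to the hip-to-shoulder
#: line, which pins the raise chain angle near 20 deg and couples
#: abduction to it; the across-midline angle is then confined to
#: ~155-165 deg, so it stays unconstrained and reads as +1 across).
NEUTRAL_RIGHT_ARM = ArmTargets(position=10.0, shoulder_raise=20.0,
                               abduction=15.0, elbow=80.0,
                               across_midline=None)

#: Left-arm neutral: the printed left-side formulas do not admit an
#: inactive abduction angle together with a small position angle (the
#: neck side-bending formula pins the left shoulder laterally), so the
#: abduction target is left unconstrained; it settles near 70 deg, which
#: the scorer counts as +1 abducted.
NEUTRAL_LEFT_ARM = ArmTargets(position=10.0, shoulder_raise=None,
                              abduction=None, elbow=80.0,
                              across_midline=None)


@dataclass(frozen=True)
class PostureSpec:
    """Target angles for every posture formula, plus noise parameters."""

    trunk_position: float | None = 0.0
    neck_position: float | None = 5.0    # signed; band 1 is (0, 10)
    neck_side_bend: float | None = 0.0   # signed departure from 90 deg
    trunk_twist: float | None = 0.0      # signed departure from 90 deg
    trunk_side_bend_right: float = 14.0  # hip chain angle (inactive <= 20)
    trunk_side_bend_left: float = 14.0
    right_arm: ArmTargets = field(default_factory=lambda: NEUTRAL_RIGHT_ARM)
    left_arm: ArmTargets = field(default_factory=lambda: NEUTRAL_LEFT_ARM)
    right_wrist: WristTargets = field(default_factory=WristTargets)
    left_wrist: WristTargets = field(default_factory=WristTargets)
    duration: float = 1.0                # seconds
    jitter_sd: float = 0.0               # degrees of angular noise
    null_rate: float = 0.0               # per-joint per-frame dropout prob

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_rate < 1.0:
            raise ValueError("null_rate must be in [0, 1)")
        for wt in (self.right_wrist, self.left_wrist):
            ps = wt.pronation_supination
            if ps is not None and not 0.0 <= ps <= 180.0:
                raise FeasibilityError(
                    "pronation-supination target outside [0, 180]"
                )
            if wt.radial_ulnar < 0.0:
                raise FeasibilityError("radial-ulnar deviation must be >= 0")


@dataclass(frozen=True)
class SessionSpec:
    """An ordered sequence of labelled posture segments."""

    segments: tuple[tuple[PostureSpec, ActivityLabel], ...]
    body_rate: float = 30.0
    hand_rate: float = 64.0
    subject: str = "S1"
    handedness: str = "right"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a session needs at least one segment")
        if sum(s.duration for s, _ in self.segments) <= 0:
            raise ValueError("total session duration must be positive")


# ---------------------------------------------------------------------------
# body pose solver

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

# limb lengths (metres; arbitrary, angles are scale-free)
_L_TRUNK = 0.45    # waist -> neck
_L_TORSO = 0.25    # waist -> torso joint
_L_HEAD = 0.25     # neck -> head
_L_HIP = 0.12      # waist -> hip
_L_SHOULDER = 0.20  # neck -> shoulder
_L_ARM = 0.25      # shoulder -> elbow, elbow -> wrist
_WAIST = np.array([0.0, 0.0, 1.0])


def _dir(theta_deg: float, psi_deg: float) -> np.ndarray:
    t, p = np.radians(theta_deg), np.radians(psi_deg)
    return np.array(
        [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
    )


def _build_skeleton(p: np.ndarray, spec: PostureSpec) -> np.ndarray:
    """Joint coordinates (16, 3) from the 18 direction parameters."""
    (alpha, thw, psw, phi, th03, ps03,
     th07, ps07, th8, ps8, th9, ps9,
     th10, ps10, th11, ps11, th12, ps12) = p
    coords = np.empty((16, 3))
    u02 = _dir(alpha, 90.0)           # trunk direction, sagittal plane
    j04 = _WAIST
    j02 = j04 + _L_TRUNK * u02
    j03 = j04 + _L_TORSO * _dir(th03, ps03)
    j01 = j02 + _L_HEAD * _dir(thw, psw)
    d05 = tilt_towards(-u02, _X, spec.trunk_side_bend_right)
    d05 = rotation_matrix(u02, phi) @ d05
    d06 = tilt_towards(-u02, -_X, spec.trunk_side_bend_left)
    j05 = j04 + _L_HIP * d05
    j06 = j04 + _L_HIP * d06
    j07 = j02 + _L_SHOULDER * _dir(th07, ps07)
    j08 = j07 + _L_ARM * _dir(th8, ps8)
    j09 = j08 + _L_ARM * _dir(th9, ps9)
    j10 = j02 + _L_SHOULDER * _dir(th10, ps10)
    j11 = j10 + _L_ARM * _dir(th11, ps11)
    j12 = j11 + _L_ARM * _dir(th12, ps12)
    coords[0:12] = [j01, j02, j03, j04, j05, j06, j07, j08, j09, j10, j11,
                    j12]
    coords[12] = j05 + [0.0, 0.0, -0.45]   # right knee
    coords[13] = j06 + [0.0, 0.0, -0.45]   # left knee
    coords[14] = coords[12] + [0.0, 0.0, -0.40]  # right foot
    coords[15] = coords[13] + [0.0, 0.0, -0.40]  # left foot
    return coords


def _chain(frame: BodyFrame, tokens) -> float:
    pts = [frame.joint(t) for t in tokens]
    return three_point_angle(*pts)


def _signed_twist(frame: BodyFrame) -> float:
    j02, j04, j05, j06 = (frame.joint(t) for t in ("02", "04", "05", "06"))
    nv = normal_vector(j02, j05, j06)
    return 90.0 - vector_angle(j04 - j06, nv)


def _body_residuals(frame: BodyFrame, spec: PostureSpec) -> list[float]:
    res: list[float] = []

    def add(target, value_fn):
        if target is None:
            return
        try:
            res.append(value_fn() - target)
        except Exception:
            res.append(1e3)  # push the solver away from degenerate poses

    add(spec.trunk_position, lambda: _body.trunk_position(frame))
    add(spec.neck_position, lambda: _body.neck_angle(frame))
    add(spec.neck_side_bend, lambda: 90.0 - _chain(frame, ("10", "02", "01")))
    add(spec.trunk_twist, lambda: _signed_twist(frame))
    for side, arm in (("right", spec.right_arm), ("left", spec.left_arm)):
        pos_t, raise_t, abd_t, low_t, acr_t = _body._ARM_TOKENS[side]
        add(arm.shoulder_raise, lambda t=raise_t: _chain(frame, t))
        add(arm.position, lambda s=side: _body.upper_arm_angle(frame, s))
        add(arm.abduction, lambda t=abd_t: _chain(frame, t))
        add(arm.elbow, lambda t=low_t: _chain(frame, t))
        add(arm.across_midline, lambda t=acr_t: _chain(frame, t))
    return res


def _sag_dir(a_deg: float) -> np.ndarray:
    """Unit direction in the sagittal (y-z) plane, tilted ``a_deg`` from
    vertical towards anterior (+y)."""
    a = np.radians(a_deg)
    return np.array([0.0, np.sin(a), np.cos(a)])


def _two_cone(p: np.ndarray, q: np.ndarray, ang_p: float, ang_q: float
              ) -> list[np.ndarray]:
    """Unit vectors at angle ``ang_p`` from axis p and ``ang_q`` from axis q
    (the intersection of two cones); [] when infeasible."""
    cp, cq = np.cos(np.radians(ang_p)), np.cos(np.radians(ang_q))
    pq = float(np.dot(p, q))
    det = 1.0 - pq * pq
    if det < 1e-12:
        return []
    a = (cp - cq * pq) / det
    b = (cq - cp * pq) / det
    c2 = (1.0 - a * a - b * b - 2.0 * a * b * pq) / det
    if c2 < -1e-10:
        return []
    c = np.sqrt(max(c2, 0.0))
    n = np.cross(p, q)
    base = a * p + b * q
    out = [base + c * n]
    if c > 0.0:
        out.append(base - c * n)
    return [d / np.linalg.norm(d) for d in out]


def _cone_dir(axis: np.ndarray, angle: float, azimuth: float) -> np.ndarray:
    """Unit vector at ``angle`` from ``axis``, rotated ``azimuth`` about it."""
    ref = _X if abs(axis[2]) > 0.9 else _Z
    d0 = tilt_towards(axis, ref, angle) if angle > 1e-12 else axis.copy()
    return rotation_matrix(axis, azimuth) @ d0


def _root_on_circle(g, lo=0.0, hi=360.0, n=181):
    """Root of a periodic scalar function over an azimuth circle, or None."""
    xs = np.linspace(lo, hi, n)
    vals = np.array([g(x) for x in xs])
    best = None
    for i in range(len(xs) - 1):
        if np.isnan(vals[i]) or np.isnan(vals[i + 1]):
            continue
        if vals[i] == 0.0:
            return xs[i]
        if vals[i] * vals[i + 1] < 0.0:
            r = brentq(g, xs[i], xs[i + 1], xtol=1e-13)
            return r
        m = abs(vals[i])
        if best is None or m < best[0]:
            best = (m, xs[i])
    return None


class _Ctx:
    """Torso context shared by the two arm constructions."""

    __slots__ = ("u02", "w", "j02", "j03", "j04", "j05", "j06", "n_ant")


def _construct_torso(spec: PostureSpec, neck_flip: bool) -> _Ctx:
    nu = spec.neck_position if spec.neck_position is not None else 5.0
    if neck_flip:
        nu = -nu
    tau = spec.trunk_position if spec.trunk_position is not None else 0.0

    def sag_angle(v) -> float:
        return float(np.degrees(np.arctan2(v[1], v[2])))

    def f(a: float) -> float:
        return sag_angle(_L_TRUNK * _sag_dir(a) + _L_HEAD * _sag_dir(a + nu)) - tau

    lo, hi = tau - abs(nu) - 1.0, tau + abs(nu) + 1.0
    while f(lo) > 0 and lo > -170:
        lo -= 10.0
    while f(hi) < 0 and hi < 170:
        hi += 10.0
    alpha = brentq(f, lo, hi, xtol=1e-13)
    ctx = _Ctx()
    ctx.u02 = _sag_dir(alpha)
    ctx.w = _sag_dir(alpha + nu)
    ctx.j04 = _WAIST
    ctx.j02 = ctx.j04 + _L_TRUNK * ctx.u02
    d05_0 = tilt_towards(-ctx.u02, _X, spec.trunk_side_bend_right)
    d06_0 = tilt_towards(-ctx.u02, -_X, spec.trunk_side_bend_left)

    def hips(phi: float) -> tuple[np.ndarray, np.ndarray]:
        # antisymmetric hip rotation about the trunk axis; preserves both
        # side-bending chain angles exactly
        r5 = rotation_matrix(ctx.u02, phi)
        r6 = rotation_matrix(ctx.u02, -phi)
        return (ctx.j04 + _L_HIP * (r5 @ d05_0),
                ctx.j04 + _L_HIP * (r6 @ d06_0))

    twist_t = spec.trunk_twist if spec.trunk_twist is not None else 0.0
    if abs(twist_t) < 1e-12:
        ctx.j05, ctx.j06 = hips(0.0)
    else:
        def g(phi: float) -> float:
            j05, j06 = hips(phi)
            try:
                nv = normal_vector(ctx.j02, j05, j06)
            except Exception:
                return np.nan  # hips collinear with the neck at this phi
            return (90.0 - vector_angle(ctx.j04 - j06, nv)) - twist_t

        phi = _root_on_circle(g, -179.0, 179.0, 359)
        if phi is None:
            raise FeasibilityError(
                f"trunk twist target {twist_t} deg unreachable with hip "
                f"chain angles {spec.trunk_side_bend_right}/"
                f"{spec.trunk_side_bend_left} deg (the twist metric is "
                f"bounded by the hip tilts)"
            )
        ctx.j05, ctx.j06 = hips(phi)

    # torso joint: placed on the waist-neck line unless the left raise
    # formula (token 19 -> torso by default) is targeted
    raise_l = spec.left_arm.shoulder_raise
    if raise_l is None or raise_l < 1e-9:
        ctx.j03 = ctx.j04 + _L_TORSO * ctx.u02
    else:
        def h(eta: float) -> float:
            d03 = tilt_towards(ctx.u02, _X, eta)
            j03 = ctx.j04 + _L_TORSO * d03
            return three_point_angle(ctx.j04, j03, ctx.j02) - raise_l

        eta = _root_on_circle(h, 0.5, 170.0, 170)
        if eta is None:
            raise FeasibilityError(
                f"left shoulder-raise target {raise_l} deg unreachable"
            )
        ctx.j03 = ctx.j04 + _L_TORSO * tilt_towards(ctx.u02, _X, eta)

    n = np.cross(ctx.j05 - ctx.j02, ctx.j06 - ctx.j02)
    ctx.n_ant = n / np.linalg.norm(n)
    return ctx


def _construct_arm(side: str, spec: PostureSpec, ctx: _Ctx
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shoulder/elbow/wrist joints for one side; exact where targeted.

    The shoulder direction lives on a cone (about the trunk axis at the
    raise angle on the right; about the head direction at 90 + side-bend
    on the left, which is what the neck side-bending formula pins); its
    azimuth, and the raise angle itself when untargeted, are searched for
    a configuration under which the elbow cone(s) intersect with the
    anterior sign the signed position target requires and the wrist
    azimuth admits the across-midline root.
    """
    arm = spec.right_arm if side == "right" else spec.left_arm
    hip = ctx.j05 if side == "right" else ctx.j06
    ups = arm.position
    abd = arm.abduction
    lam = arm.elbow if arm.elbow is not None else 80.0
    if side == "right":
        cone_axis = ctx.u02
        if arm.shoulder_raise is not None:
            cone_angles = [arm.shoulder_raise]
        else:
            cone_angles = list(np.linspace(20.0, 170.0, 16))
    else:
        sb = spec.neck_side_bend if spec.neck_side_bend is not None else 0.0
        cone_axis = ctx.w
        cone_angles = [90.0 + sb]
    want_sign = 0.0 if ups is None else np.sign(ups)

    def elbow_candidates(d_sh, u1) -> list[np.ndarray]:
        if ups is None and abd is None:
            base = _cone_dir(-ctx.u02, 20.0, 90.0)
            return [rotation_matrix(-ctx.u02, chi) @ base
                    for chi in np.linspace(0.0, 330.0, 12)]
        if ups is None:
            return [_cone_dir(d_sh, abd, chi)
                    for chi in np.linspace(0.0, 330.0, 12)]
        if abd is None:
            g0 = _cone_dir(u1, 180.0 - abs(ups), 0.0)
            return [rotation_matrix(u1, chi) @ g0
                    for chi in np.linspace(0.0, 345.0, 24)]
        return _two_cone(u1, d_sh, 180.0 - abs(ups), abd)

    def wrist_dir(j_sh, j_el, d_el) -> np.ndarray | None:
        if arm.across_midline is None:
            return _cone_dir(d_el, lam, 0.0)
        # vectorised coarse scan of the across angle over the wrist cone,
        # then an exact bracketing root
        ref = _X if abs(d_el[2]) > 0.9 else _Z
        e1 = tilt_towards(d_el, ref, 90.0)
        e2 = np.cross(d_el, e1)
        chis = np.radians(np.linspace(0.0, 360.0, 49))
        cl, sl = np.cos(np.radians(lam)), np.sin(np.radians(lam))
        dirs = (cl * d_el[None, :]
                + sl * (np.cos(chis)[:, None] * e1[None, :]
                        + np.sin(chis)[:, None] * e2[None, :]))
        v = (j_el[None, :] + _L_ARM * dirs) - ctx.j03
        u = ctx.j03 - j_sh
        cross = np.cross(np.broadcast_to(u, v.shape), v)
        ang = np.degrees(np.arctan2(np.linalg.norm(cross, axis=1), v @ u))
        vals = ang - arm.across_midline
        idx = np.nonzero(vals[:-1] * vals[1:] <= 0.0)[0]
        if len(idx) == 0:
            return None

        def g(chi: float) -> float:
            j_wr = j_el + _L_ARM * _cone_dir(d_el, lam, chi)
            return three_point_angle(j_sh, ctx.j03, j_wr) - arm.across_midline

        lo, hi = np.degrees(chis[idx[0]]), np.degrees(chis[idx[0] + 1])
        if g(lo) == 0.0:
            return _cone_dir(d_el, lam, lo)
        chi = brentq(g, lo, hi, xtol=1e-13)
        return _cone_dir(d_el, lam, chi)

    fallback = None  # zero-sign-margin solution kept as a last resort
    for cone_ang in cone_angles:
        for psi in np.linspace(0.0, 356.0, 90):
            d_sh = _cone_dir(cone_axis, cone_ang, psi)
            j_sh = ctx.j02 + _L_SHOULDER * d_sh
            u1 = hip - j_sh
            u1 = u1 / np.linalg.norm(u1)
            for d_el in elbow_candidates(d_sh, u1):
                s = float(np.dot(d_el, ctx.n_ant))
                sign_ok = (want_sign == 0.0 or abs(ups) < 1e-9
                           or np.sign(s) == want_sign)
                if not sign_ok and abs(s) > 1e-9:
                    continue
                j_el = j_sh + _L_ARM * d_el
                d_wr = wrist_dir(j_sh, j_el, d_el)
                if d_wr is None:
                    continue
                j_wr = j_el + _L_ARM * d_wr
                if sign_ok and abs(s) > 1e-6:
                    return j_sh, j_el, j_wr
                if fallback is None:
                    fallback = (j_sh, j_el, j_wr)
    if fallback is not None:
        return fallback
    raise FeasibilityError(
        f"{side} arm targets (position={ups}, abduction={abd}, "
        f"elbow={lam}, across={arm.across_midline}) are jointly "
        f"unreachable under the printed formulas"
    )


def _construct_pose(spec: PostureSpec, neck_flip: bool) -> np.ndarray:
    ctx = _construct_torso(spec, neck_flip)
    coords = np.empty((16, 3))
    j01 = ctx.j02 + _L_HEAD * ctx.w
    j07, j08, j09 = _construct_arm("right", spec, ctx)
    j10, j11, j12 = _construct_arm("left", spec, ctx)
    coords[0:12] = [j01, ctx.j02, ctx.j03, ctx.j04, ctx.j05, ctx.j06,
                    j07, j08, j09, j10, j11, j12]
    coords[12] = ctx.j05 + [0.0, 0.0, -0.45]
    coords[13] = ctx.j06 + [0.0, 0.0, -0.45]
    coords[14] = coords[12] + [0.0, 0.0, -0.40]
    coords[15] = coords[13] + [0.0, 0.0, -0.40]
    return coords


def _params_from_pose(coords: np.ndarray, spec: PostureSpec) -> np.ndarray:
    """Recover the 18 direction parameters from explicit joint coordinates
    (for seeding the least-squares fallback)."""

    def sph(v: np.ndarray) -> tuple[float, float]:
        u = v / np.linalg.norm(v)
        return (float(np.degrees(np.arccos(np.clip(u[2], -1, 1)))),
                float(np.degrees(np.arctan2(u[1], u[0]))))

    (j01, j02, j03, j04, j05, j06, j07, j08, j09, j10, j11, j12) = coords[:12]
    u02 = (j02 - j04) / np.linalg.norm(j02 - j04)
    alpha = float(np.degrees(np.arctan2(u02[1], u02[2])))
    thw, psw = sph(j01 - j02)
    th03, ps03 = sph(j03 - j04)
    d05_0 = tilt_towards(-u02, _X, spec.trunk_side_bend_right)
    d05 = (j05 - j04) / np.linalg.norm(j05 - j04)
    # twist angle about u02 between the untwisted and actual right hip
    a = d05_0 - u02 * np.dot(u02, d05_0)
    b = d05 - u02 * np.dot(u02, d05)
    phi = float(np.degrees(np.arctan2(np.dot(np.cross(a, b), u02),
                                      np.dot(a, b))))
    vals = [alpha, thw, psw, phi, th03, ps03]
    for prox, dist in ((j02, j07), (j07, j08), (j08, j09),
                       (j02, j10), (j10, j11), (j11, j12)):
        vals.extend(sph(dist - prox))
    return np.array(vals)


def _residual_err(coords: np.ndarray, spec: PostureSpec) -> float:
    frame = BodyFrame(0.0, coords, DEFAULT_BODY_REGISTRY)
    res = _body_residuals(frame, spec)
    return float(np.max(np.abs(res))) if res else 0.0


@functools.lru_cache(maxsize=256)
def _solve_body_cached(spec: PostureSpec) -> np.ndarray:
    best: tuple[float, np.ndarray] | None = None
    for neck_flip in (False, True):
        try:
            coords = _construct_pose(spec, neck_flip)
        except FeasibilityError:
            continue
        err = _residual_err(coords, spec)
        if best is None or err < best[0]:
            best = (err, coords)
        if err < TOL_DEG:
            return coords
    if best is None:
        # no constructive pose at all: seed the numeric fallback from a
        # relaxed construction (all arm targets dropped)
        relaxed = replace(
            spec,
            right_arm=ArmTargets(None, None, None, None, None),
            left_arm=ArmTargets(None, None, None, None, None),
        )
        try:
            coords = _construct_pose(relaxed, False)
            best = (_residual_err(coords, spec), coords)
        except FeasibilityError as exc:
            raise FeasibilityError(
                "no constructive pose realises the targeted angles; the "
                "combination is geometrically infeasible under the "
                "printed formulas"
            ) from exc
    # least-squares polish from the constructive seed
    p0 = _params_from_pose(best[1], spec)
    n_res = len(_body_residuals(
        BodyFrame(0.0, best[1], DEFAULT_BODY_REGISTRY), spec
    ))

    def fun(p: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(p)):
            return np.full(n_res, 1e3)
        frame = BodyFrame(0.0, _build_skeleton(p, spec),
                          DEFAULT_BODY_REGISTRY)
        return np.asarray(_body_residuals(frame, spec))

    rng = np.random.default_rng(97531)  # deterministic multi-start
    for attempt in range(6):
        start = p0 if attempt == 0 else p0 + rng.normal(0.0, 10.0, p0.shape)
        sol = least_squares(fun, start, method="trf", max_nfev=400)
        sol = least_squares(fun, sol.x, method="trf", jac="3-point",
                            ftol=1e-15, xtol=None, gtol=None, max_nfev=200)
        coords = _build_skeleton(sol.x, spec)
        err = _residual_err(coords, spec)
        if err < best[0]:
            best = (err, coords)
        if err < TOL_DEG:
            return coords
    raise FeasibilityError(
        f"could not realise the targeted angles (worst residual "
        f"{best[0]:.3g} deg); the target combination is likely "
        f"geometrically infeasible under the printed formulas"
    )


def solve_body_pose(spec: PostureSpec) -> np.ndarray:
    """Body joint coordinates (16, 3) realising the spec's targets."""
    # cache on the body-relevant fields only
    norm = replace(spec, right_wrist=WristTargets(),
                   left_wrist=WristTargets(), duration=1.0,
                   jitter_sd=0.0, null_rate=0.0)
    return _solve_body_cached(norm).copy()


# ---------------------------------------------------------------------------
# hand pose construction (closed form)

def _hand_template() -> np.ndarray:
    """Flat neutral hand in the z=0 plane, millimetre scale.

    Joint layout follows five-per-finger blocks (thumb 00-04, index 05-09,
    middle 10-14, ring 15-19, pinky 20-24); only the five scoring joints
    have meaningful positions, the rest are plausible filler.  The palm
    normal of this template points +z; it doubles as the calibration
    ("initial position") pose.
    """
    t = np.zeros((25, 3))
    # thumb chain; 04 = thumb metacarpal endpoint (scoring joint)
    t[0] = (-15.0, 10.0, 0.0)
    t[1] = (-25.0, 25.0, 0.0)
    t[2] = (-32.0, 38.0, 0.0)
    t[3] = (-37.0, 50.0, 0.0)
    t[4] = (-40.0, 60.0, 0.0)
    # index chain; 05 = distal-phalanx start point (scoring joint)
    t[5] = (-20.0, 130.0, 0.0)
    t[6] = (-22.0, 110.0, 0.0)
    t[7] = (-24.0, 85.0, 0.0)
    t[8] = (-25.0, 60.0, 0.0)
    t[9] = (-19.0, 145.0, 0.0)
    # middle chain; 13 = proximal-phalanx endpoint, 14 = metacarpal endpoint
    t[10] = (0.0, 150.0, 0.0)
    t[11] = (0.0, 120.0, 0.0)
    t[12] = (0.0, 100.0, 0.0)
    t[13] = (0.0, 140.0, 0.0)
    t[14] = (0.0, 80.0, 0.0)
    # ring chain
    t[15] = (20.0, 125.0, 0.0)
    t[16] = (21.0, 105.0, 0.0)
    t[17] = (22.0, 82.0, 0.0)
    t[18] = (23.0, 58.0, 0.0)
    t[19] = (24.0, 135.0, 0.0)
    # pinky chain; 24 = metacarpal endpoint (scoring joint)
    t[20] = (38.0, 115.0, 0.0)
    t[21] = (39.0, 98.0, 0.0)
    t[22] = (40.0, 80.0, 0.0)
    t[23] = (40.0, 70.0, 0.0)
    t[24] = (40.0, 60.0, 0.0)
    return t


HAND_TEMPLATE = _hand_template()
#: palm-plane normal of the neutral template (the calibration normal).
TEMPLATE_NORMAL = normal_vector(HAND_TEMPLATE[13], HAND_TEMPLATE[4],
                                HAND_TEMPLATE[24])
#: neutral chain angle of the radial-ulnar formula joints.
TEMPLATE_NEUTRAL_RU = _wrist.three_point_angle(
    HAND_TEMPLATE[5], HAND_TEMPLATE[4], HAND_TEMPLATE[24]
)


def solve_hand_pose(targets: WristTargets) -> np.ndarray:
    """Hand joint coordinates (25, 3) realising the wrist targets exactly.

    Construction: reposition the index scoring joint in-plane for the
    radial-ulnar deviation, lift the middle proximal endpoint out of plane
    for flexion-extension, then rigidly rotate the whole hand about an
    axis through the sensor origin until the palm normal sits at the
    pronation-supination angle from the calibration normal (rigid
    rotations about the origin preserve the other two quantities).
    """
    pts = HAND_TEMPLATE.copy()
    # radial-ulnar: rotate the (x04 - x05) segment in-plane
    dev = targets.radial_ulnar
    if dev > 0.0:
        u = pts[24] - pts[4]
        v = pts[4] - pts[5]
        signed = np.degrees(
            np.arctan2(u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1])
        )
        target_abs = TEMPLATE_NEUTRAL_RU + dev
        if target_abs > 180.0:
            target_abs = TEMPLATE_NEUTRAL_RU - dev
            if target_abs < 0.0:
                raise FeasibilityError(
                    f"radial-ulnar deviation {dev} deg unreachable"
                )
        new_signed = np.copysign(target_abs, signed)
        r = np.radians(new_signed)
        uhat = u / np.linalg.norm(u)
        vnew = (np.array([uhat[0] * np.cos(r) - uhat[1] * np.sin(r),
                          uhat[0] * np.sin(r) + uhat[1] * np.cos(r), 0.0])
                * np.linalg.norm(v))
        pts[5] = pts[4] - vnew
    # flexion-extension: lift x13 (and cosmetic mid-finger joints)
    fe = targets.flexion_extension
    if fe != 0.0:
        R = rotation_matrix(_X, fe)
        for j in (10, 11, 13):
            pts[j] = R @ pts[j]
    # pronation-supination: rigid rotation about an origin axis (skipped
    # when unconstrained: the palm then sits wherever the lift put it)
    ps = targets.pronation_supination
    if ps is not None:
        n0 = normal_vector(pts[13], pts[4], pts[24])
        theta0 = vector_angle(n0, TEMPLATE_NORMAL)
        if abs(ps - theta0) > 1e-12:
            cross = np.cross(TEMPLATE_NORMAL, n0)
            axis = cross if np.linalg.norm(cross) > 1e-9 else _Y
            done = False
            for gamma in (ps - theta0, theta0 - ps):
                cand = pts @ rotation_matrix(axis, gamma).T
                n1 = normal_vector(cand[13], cand[4], cand[24])
                if abs(vector_angle(n1, TEMPLATE_NORMAL) - ps) < TOL_DEG:
                    pts = cand
                    done = True
                    break
            if not done:
                raise FeasibilityError(
                    f"pronation-supination target {ps} deg unreachable"
                )
    _verify_hand(pts, targets)
    return pts


def _verify_hand(pts: np.ndarray, targets: WristTargets) -> None:
    """Measure the constructed hand with the scoring functions and check
    every targeted quantity (including the flexion sign) within TOL_DEG."""
    cal = _template_calibration()
    frame = HandFrame(0.0, np.vstack([pts, pts]), DEFAULT_HAND_REGISTRY)
    wa = _wrist.wrist_angles(frame, "right", cal)
    problems = []
    if wa is None:
        problems.append("pose unscorable")
    else:
        if abs(wa.flexion_extension - targets.flexion_extension) > TOL_DEG:
            problems.append(
                f"flexion-extension {wa.flexion_extension:.4f} != "
                f"{targets.flexion_extension} (the palm rotation needed for "
                f"the pronation-supination target flips the up/down sign)"
            )
        if abs(wa.radial_ulnar - targets.radial_ulnar) > TOL_DEG:
            problems.append(f"radial-ulnar {wa.radial_ulnar:.4f} != "
                            f"{targets.radial_ulnar}")
        ps = targets.pronation_supination
        if ps is not None and abs(wa.pronation_supination - ps) > TOL_DEG:
            problems.append(f"pronation-supination "
                            f"{wa.pronation_supination:.4f} != {ps}")
    if problems:
        raise FeasibilityError(
            "wrist targets not jointly realisable: " + "; ".join(problems)
        )


# ---------------------------------------------------------------------------
# ground truth

def _template_calibration() -> _wrist.CalibrationPose:
    sides = {
        side: _wrist.SideCalibration(TEMPLATE_NORMAL.copy(),
                                     TEMPLATE_NEUTRAL_RU, 0)
        for side in ("left", "right")
    }
    return _wrist.CalibrationPose(sides)


def achieved_angles(spec: PostureSpec) -> dict[str, float]:
    """Measure every formula angle on the noise-free constructed pose."""
    frame = BodyFrame(0.0, solve_body_pose(spec), DEFAULT_BODY_REGISTRY)
    cal = _template_calibration()
    out: dict[str, float] = {
        "trunk_position": _body.trunk_position(frame),
        "neck_position": _body.neck_angle(frame),
        "neck_side_bend": 90.0 - _chain(frame, ("10", "02", "01")),
        "trunk_twist": _signed_twist(frame),
        "trunk_side_bend_right": _chain(frame, ("02", "04", "05")),
        "trunk_side_bend_left": _chain(frame, ("02", "04", "06")),
    }
    for side in ("right", "left"):
        pos_t, raise_t, abd_t, low_t, acr_t = _body._ARM_TOKENS[side]
        out[f"upper_arm_{side}"] = _body.upper_arm_angle(frame, side)
        out[f"shoulder_raise_{side}"] = _chain(frame, raise_t)
        out[f"abduction_{side}"] = _chain(frame, abd_t)
        out[f"lower_arm_{side}"] = _chain(frame, low_t)
        out[f"across_midline_{side}"] = _chain(frame, acr_t)
    for side, wt in (("right", spec.right_wrist), ("left", spec.left_wrist)):
        hand = solve_hand_pose(wt)
        hf = HandFrame(0.0, np.vstack([hand, hand]), DEFAULT_HAND_REGISTRY)
        wa = _wrist.wrist_angles(hf, side, cal)
        out[f"flexion_extension_{side}"] = wa.flexion_extension
        out[f"radial_ulnar_{side}"] = wa.radial_ulnar
        out[f"pronation_supination_{side}"] = wa.pronation_supination
    return out


def true_scores(spec: PostureSpec,
                neutral_band: float = 1.0,
                standing_unsupported: bool = True) -> dict[str, int | str]:
    """RULA scores implied by the achieved angles (the oracle values)."""
    ang = achieved_angles(spec)
    s: dict[str, int | str] = {}
    for side in ("left", "right"):
        ua = min(
            _body.upper_arm_base(ang[f"upper_arm_{side}"])
            + (1 if ang[f"shoulder_raise_{side}"] > 90.0 else 0)
            + (1 if ang[f"abduction_{side}"] > 20.0 else 0), 6,
        )
        la = min(
            _body.lower_arm_base(ang[f"lower_arm_{side}"])
            + (1 if ang[f"across_midline_{side}"] > 90.0 else 0)
            + (1 if ang[f"upper_arm_{side}"] > 30.0 else 0), 3,
        )
        wp = _wrist.wrist_position_score(
            ang[f"flexion_extension_{side}"], ang[f"radial_ulnar_{side}"],
            neutral_band,
        )
        wt = _wrist.wrist_twist_score(ang[f"pronation_supination_{side}"])
        s[f"upper_arm_{side}"] = ua
        s[f"lower_arm_{side}"] = la
        s[f"wrist_position_{side}"] = wp
        s[f"wrist_twist_{side}"] = wt
    s["neck"] = min(
        _body.neck_base(ang["neck_position"])
        + (1 if abs(ang["neck_side_bend"]) > 20.0 else 0), 6,
    )
    s["trunk"] = min(
        _body.trunk_base(ang["trunk_position"], neutral_band)
        + (1 if abs(ang["trunk_twist"]) > 20.0 else 0)
        + (1 if (ang["trunk_side_bend_right"] > 20.0
                 or ang["trunk_side_bend_left"] > 20.0) else 0), 6,
    )
    s["legs"] = 2 if standing_unsupported else 1
    s["A_left"] = score_A(s["upper_arm_left"], s["lower_arm_left"],
                          s["wrist_position_left"], s["wrist_twist_left"])
    s["A_right"] = score_A(s["upper_arm_right"], s["lower_arm_right"],
                           s["wrist_position_right"], s["wrist_twist_right"])
    s["A_max"] = score_A(
        max(s["upper_arm_left"], s["upper_arm_right"]),
        max(s["lower_arm_left"], s["lower_arm_right"]),
        max(s["wrist_position_left"], s["wrist_position_right"]),
        max(s["wrist_twist_left"], s["wrist_twist_right"]),
    )
    s["B"] = score_B(s["neck"], s["trunk"], s["legs"])
    s["grand_left"] = grand_score(s["A_left"], s["B"])
    s["grand_right"] = grand_score(s["A_right"], s["B"])
    s["grand_general"] = grand_score(s["A_max"], s["B"])
    s["risk_left"] = risk_level(s["grand_left"])
    s["risk_right"] = risk_level(s["grand_right"])
    s["risk_general"] = risk_level(s["grand_general"])
    return s


# ---------------------------------------------------------------------------
# frame generation

def _jitter_and_nulls(coords: np.ndarray, root: np.ndarray, jitter_sd: float,
                      null_rate: float, rng: np.random.Generator
                      ) -> np.ndarray:
    out = coords.copy()
    if jitter_sd > 0.0:
        for j in range(len(out)):
            axis = rng.normal(size=3)
            while np.linalg.norm(axis) < 1e-12:
                axis = rng.normal(size=3)
            angle = rng.normal(0.0, jitter_sd)
            R = rotation_matrix(axis, angle)
            out[j] = R @ (out[j] - root) + root
    if null_rate > 0.0:
        drop = rng.random(len(out)) < null_rate
        out[drop] = np.nan
    return out


def make_posture_frames(spec: PostureSpec,
                        body_rate: float = 30.0,
                        hand_rate: float = 64.0,
                        t0: float = 0.0,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[Stream, Stream]:
    """Generate (body stream, hand stream) holding the spec's pose.

    Joints are placed so every targeted formula evaluates to its target
    within 1e-6 deg before noise; jitter (small random rotations about the
    skeleton root) and dropouts are applied afterwards, driven by ``rng``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    body_pose = solve_body_pose(spec)
    hand_pose = np.vstack([
        solve_hand_pose(spec.left_wrist), solve_hand_pose(spec.right_wrist)
    ])
    n_body = max(1, int(round(spec.duration * body_rate)))
    n_hand = max(1, int(round(spec.duration * hand_rate)))
    body_ts = t0 + np.arange(n_body) / body_rate
    hand_ts = t0 + np.arange(n_hand) / hand_rate
    body_root = body_pose[3]  # waist
    hand_root = np.zeros(3)   # sensor origin
    body_frames = np.stack([
        _jitter_and_nulls(body_pose, body_root, spec.jitter_sd,
                          spec.null_rate, rng)
        for _ in range(n_body)
    ])
    hand_frames = np.stack([
        _jitter_and_nulls(hand_pose, hand_root, spec.jitter_sd,
                          spec.null_rate, rng)
        for _ in range(n_hand)
    ])
    body = Stream(body_ts, body_frames, "body", DEFAULT_BODY_REGISTRY,
                  body_rate)
    hand = Stream(hand_ts, hand_frames, "hand", DEFAULT_HAND_REGISTRY,
                  hand_rate)
    return body, hand


def make_session(spec: SessionSpec, outdir, seed: int = 0) -> dict[str, Path]:
    """Write body/hand/label/ground-truth CSVs for a labelled session.

    Returns the four file paths.  The ground-truth file holds one row per
    segment with its time span, labels, achieved formula angles and true
    scores; wrist targets are measured against the neutral hand template,
    which is also the pose a first neutral segment presents to the
    pipeline's calibration step.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    body_parts, hand_parts, label_rows, truth_rows = [], [], [], []
    t = 0.0
    for pspec, label in spec.segments:
        body, hand = make_posture_frames(
            pspec, spec.body_rate, spec.hand_rate, t0=t, rng=rng
        )
        body_parts.append(body)
        hand_parts.append(hand)
        label_rows.append((t, label.high, label.middle, label.low))
        row: dict = {"t_start": t, "t_end": t + pspec.duration,
                     "high": label.high, "middle": label.middle,
                     "low": label.low}
        row.update({f"angle_{k}": v for k, v in achieved_angles(pspec).items()})
        row.update({f"score_{k}": v for k, v in true_scores(pspec).items()})
        truth_rows.append(row)
        t += pspec.duration
    body_all = Stream(
        np.concatenate([b.timestamps for b in body_parts]),
        np.concatenate([b.coords for b in body_parts]),
        "body", DEFAULT_BODY_REGISTRY, spec.body_rate,
        subject=spec.subject, handedness=spec.handedness,
    )
    hand_all = Stream(
        np.concatenate([h.timestamps for h in hand_parts]),
        np.concatenate([h.coords for h in hand_parts]),
        "hand", DEFAULT_HAND_REGISTRY, spec.hand_rate,
        subject=spec.subject, handedness=spec.handedness,
    )
    paths = {
        "body": outdir / "body.csv",
        "hand": outdir / "hand.csv",
        "labels": outdir / "labels.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_body_stream(paths["body"], body_all)
    write_hand_stream(paths["hand"], hand_all)
    write_labels(paths["labels"], label_rows)
    pd.DataFrame(truth_rows).to_csv(paths["ground_truth"], index=False)
    return paths


def demo_session(segment_duration: float = 2.0,
                 jitter_sd: float = 0.0,
                 null_rate: float = 0.0) -> SessionSpec:
    """A built-in five-activity session mirroring a drawer-assembly run.

    The first segment is neutral, so pipeline calibration on the first
    valid frame coincides with the template the wrist targets are measured
    against.
    """
    neutral = PostureSpec(duration=segment_duration, jitter_sd=jitter_sd,
                          null_rate=null_rate)
    segs = (
        (neutral,
         ActivityLabel("prepare the workspace", "clear table", "grasp")),
        (replace(neutral, trunk_position=25.0,
                 right_wrist=WristTargets(flexion_extension=20.0)),
         ActivityLabel("assemble side panel", "attach pin", "assemble")),
        (replace(neutral,
                 right_arm=ArmTargets(position=60.0, shoulder_raise=None,
                                      abduction=None, elbow=40.0,
                                      across_midline=None),
                 right_wrist=WristTargets(flexion_extension=-20.0,
                                          radial_ulnar=20.0)),
         ActivityLabel("assemble main panel", "pick panel",
                       "transport loaded")),
        (replace(neutral, trunk_position=45.0, neck_position=25.0,
                 right_wrist=WristTargets(pronation_supination=130.0)),
         ActivityLabel("integrate panel", "join panels", "position")),
        (replace(neutral,
                 right_arm=replace(NEUTRAL_RIGHT_ARM, position=100.0,
                                   shoulder_raise=None, abduction=None),
                 right_wrist=WristTargets(pronation_supination=90.0)),
         ActivityLabel("slide the mid-panel", "slide panel",
                       "release load")),
    )
    return SessionSpec(segments=segs)


def load_session_spec(path) -> SessionSpec:
    """Session spec from YAML: rates, subject, and a list of segments with
    posture targets (missing targets fall back to the neutral defaults)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    segs = []
    for seg in data.get("segments", []):
        label = ActivityLabel(
            high=seg.get("high", "prepare the workspace"),
            middle=seg.get("middle", ""),
            low=seg.get("low", ""),
        )
        kwargs = {
            k: v for k, v in seg.items()
            if k in PostureSpec.__dataclass_fields__
            and k not in ("right_arm", "left_arm", "right_wrist",
                          "left_wrist")
        }
        for arm_key, neutral in (("right_arm", NEUTRAL_RIGHT_ARM),
                                 ("left_arm", NEUTRAL_LEFT_ARM)):
            if arm_key in seg:
                kwargs[arm_key] = replace(neutral, **seg[arm_key])
        for wkey in ("right_wrist", "left_wrist"):
            if wkey in seg:
                kwargs[wkey] = WristTargets(**seg[wkey])
        segs.append((PostureSpec(**kwargs), label))
    session_kwargs = {
        k: v for k, v in data.items()
        if k in SessionSpec.__dataclass_fields__ and k != "segments"
    }
    return SessionSpec(segments=tuple(segs), **session_kwargs)


# score domains for the expert-file perturbation, per segment kind
_SCORE_DOMAIN = {
    "upper_arm": (1, 6), "lower_arm": (1, 3), "wrist_position": (1, 4),
    "wrist_twist": (1, 2), "neck": (1, 6), "trunk": (1, 6), "legs": (1, 2),
    "A": (1, 9), "B": (1, 9), "grand": (1, 7),
}


def make_expert_file(scores, path, stride: int = 10,
                     disagreement_rate: float = 0.0, seed: int = 0):
    """Derive an expert-label CSV from a per-frame score table.

    Every ``stride``-th row is emitted as long-form expert rows
    (timestamp, segment, side, score) for all report strata; with
    probability ``disagreement_rate`` a score is perturbed by +/-1,
    clipped to its segment's domain.  Mirrors the labelling cadence of a
    human rater annotating every k-th fused frame.
    """
    import pandas as pd

    from .evaluation import REPORT_COLUMNS

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(0, len(scores), stride):
        frame_row = scores.iloc[i]
        for (segment, side), col in REPORT_COLUMNS.items():
            score = int(frame_row[col])
            if disagreement_rate > 0.0 and rng.random() < disagreement_rate:
                lo, hi = _SCORE_DOMAIN[segment]
                score = int(np.clip(score + rng.choice([-1, 1]), lo, hi))
            rows.append((float(frame_row["timestamp"]), segment, side, score))
    df = pd.DataFrame(rows, columns=["timestamp", "segment", "side", "score"])
    df.to_csv(path, index=False)
    return df
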