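"""Skeleton data model: joint registries, frames and streams.

Two sensors feed the pipeline.  A body-tracking camera reports 16 body
joints per frame at a nominal 30 Hz; a hand-tracking sensor reports 25
joints per hand at a nominal 64 Hz.  Every joint is a 3D coordinate in the
sensor frame; a joint can be missing in a frame (a *null* joint), which is
represented as a NaN triple so that whole streams live in dense numpy
arrays.

The body registry maps the two-digit index tokens used by the posture
formulas ("01".."16", plus the alias "19") to anatomical names and column
positions.  The default anatomical mapping is a documented convention
inferred from how the formulas use each token (e.g. 01=head, 02=neck,
04=waist); it can be overridden from configuration, including the identity
of the alias token "19" (default: the left shoulder, token "10").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "BodyJointRegistry",
    "HandJointRegistry",
    "DEFAULT_BODY_REGISTRY",
    "DEFAULT_HAND_REGISTRY",
    "THERBLIGS",
    "HIGH_LEVEL_ACTIVITIES",
    "ActivityLabel",
    "BodyFrame",
    "HandFrame",
    "Stream",
]


class ValidationError(ValueError):
    """Raised when stream or registry invariants are violated."""


# ---------------------------------------------------------------------------
# registries

#: Default anatomical identity of the 16 body-joint tokens.
BODY_JOINT_NAMES: dict[str, str] = {
    "01": "head",
    "02": "neck",
    "03": "torso",
    "04": "waist",
    "05": "right_hip",
    "06": "left_hip",
    "07": "right_shoulder",
    "08": "right_elbow",
    "09": "right_wrist",
    "10": "left_shoulder",
    "11": "left_elbow",
    "12": "left_wrist",
    "13": "right_knee",
    "14": "left_knee",
    "15": "right_foot",
    "16": "left_foot",
}

#: Body tokens referenced by at least one posture formula; frames in which
#: any of these is null cannot be scored.
BODY_REQUIRED_TOKENS: frozenset[str] = frozenset(
    {"01", "02", "03", "04", "05", "06", "07", "08", "09", "10", "11", "12", "19"}
)


@dataclass(frozen=True)
class BodyJointRegistry:
    """Mapping from body-joint index tokens to names and column positions."""

    names: Mapping[str, str] = field(
        default_factory=lambda: dict(BODY_JOINT_NAMES)
    )
    #: alias tokens resolving to physical tokens.  The formula token "19"
    #: (left shoulder-raise row only) has no published identity; the
    #: provisional default maps it to the torso joint "03", under which the
    #: left raise formula measures the torso joint's departure from the
    #: waist-neck line and reads ~0 for an upright skeleton.  Mapping it to
    #: the left shoulder ("10") instead makes the formula read >150 deg for
    #: any laterally placed shoulder, i.e. permanently "raised".
    #: Config-overridable either way.
    aliases: Mapping[str, str] = field(default_factory=lambda: {"19": "03"})
    #: unit vector of the body-sensor vertical axis.
    vertical_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.names) != 16:
            raise ValidationError(
                f"body registry must define exactly 16 joints, got {len(self.names)}"
            )
        axis = np.asarray(self.vertical_axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0):
            raise ValidationError("vertical axis must have unit norm")
        for token in BODY_REQUIRED_TOKENS:
            self.resolve(token)  # raises if unresolvable

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.names)

    def resolve(self, token: str) -> str:
        """Follow aliases to a physical token."""
        seen = set()
        while token in self.aliases:
            if token in seen:
                raise ValidationError(f"alias cycle at body token {token!r}")
            seen.add(token)
            token = self.aliases[token]
        if token not in self.names:
            raise ValidationError(f"unregistered body joint token {token!r}")
        return token

    def column(self, token: str) -> int:
        return self.tokens.index(self.resolve(token))

    def with_vertical_axis(self, axis: Sequence[float]) -> "BodyJointRegistry":
        return replace(self, vertical_axis=tuple(float(x) for x in axis))


#: Hand-joint roles the wrist formulas need, as two-digit per-side labels.
HAND_ROLES: dict[str, str] = {
    "thumb_mc_end": "04",    # thumb metacarpal endpoint
    "index_dp_start": "05",  # index-finger distal-phalanx start point
    "middle_pp_end": "13",   # middle-finger proximal-phalanx endpoint
    "middle_mc_end": "14",   # middle-finger metacarpal endpoint
    "pinky_mc_end": "24",    # pinky metacarpal endpoint
}


@dataclass(frozen=True)
class HandJointRegistry:
    """25 joints per hand, labelled L00-L24 and R00-R24."""

    roles: Mapping[str, str] = field(default_factory=lambda: dict(HAND_ROLES))

    n_per_hand: int = 25

    def __post_init__(self) -> None:
        for role, label in self.roles.items():
            if label not in self.hand_labels():
                raise ValidationError(
                    f"hand role {role!r} maps to unknown label {label!r}"
                )

    def hand_labels(self) -> tuple[str, ...]:
        return tuple(f"{i:02d}" for i in range(self.n_per_hand))

    @property
    def columns(self) -> tuple[str, ...]:
        """Full column order: L00..L24 then R00..R24."""
        return tuple(
            f"{side}{lab}" for side in ("L", "R") for lab in self.hand_labels()
        )

    def column(self, side: str, label: str) -> int:
        side = side.lower()
        if side not in ("left", "right"):
            raise ValidationError(f"unknown hand side {side!r}")
        if label not in self.hand_labels():
            raise ValidationError(f"unregistered hand joint label {label!r}")
        base = 0 if side == "left" else self.n_per_hand
        return base + int(label)

    def role_column(self, side: str, role: str) -> int:
        return self.column(side, self.roles[role])


DEFAULT_BODY_REGISTRY = BodyJointRegistry()
DEFAULT_HAND_REGISTRY = HandJointRegistry()


# ---------------------------------------------------------------------------
# activity labels

THERBLIGS: frozenset[str] = frozenset(
    {"grasp", "transport loaded", "assemble", "inspect", "position",
     "release load"}
)

HIGH_LEVEL_ACTIVITIES: frozenset[str] = frozenset(
    {"assemble side panel", "assemble main panel", "integrate panel",
     "prepare the workspace", "slide the mid-panel"}
)


@dataclass(frozen=True)
class ActivityLabel:
    """Three-level activity annotation (high / middle / low).

    The low level is restricted to the six Therbligs relevant to assembly
    work; the middle level is free text bridging the two.
    """

    high: str
    middle: str = ""
    low: str = ""

    def __post_init__(self) -> None:
        if self.low and self.low not in THERBLIGS:
            raise ValidationError(
                f"low-level label {self.low!r} is not one of the six Therbligs"
            )


# ---------------------------------------------------------------------------
# frames and streams

def _joint_or_none(coords: np.ndarray) -> np.ndarray | None:
    return None if np.any(np.isnan(coords)) else coords


@dataclass(frozen=True)
class BodyFrame:
    """One timestamped set of 16 body-joint coordinates (NaN = null)."""

    timestamp: float
    coords: np.ndarray  # (16, 3)
    registry: BodyJointRegistry = DEFAULT_BODY_REGISTRY

    def joint(self, token: str) -> np.ndarray | None:
        """Coordinates of a joint by formula token, or None if null."""
        return _joint_or_none(self.coords[self.registry.column(token)])


@dataclass(frozen=True)
class HandFrame:
    """One timestamped set of 25 left + 25 right hand-joint coordinates."""

    timestamp: float
    coords: np.ndarray  # (50, 3): L00..L24, R00..R24
    registry: HandJointRegistry = DEFAULT_HAND_REGISTRY

    def joint(self, side: str, label: str) -> np.ndarray | None:
        return _joint_or_none(self.coords[self.registry.column(side, label)])

    def role(self, side: str, role: str) -> np.ndarray | None:
        return _joint_or_none(
            self.coords[self.registry.role_column(side, role)]
        )


@dataclass
class Stream:
    """An ordered sequence of frames of one kind, as dense arrays.

    ``coords`` has shape (n_frames, n_joints, 3) with NaN triples for null
    joints; ``kind`` is "body" or "hand".  Timestamps must be strictly
    increasing.
    """

    timestamps: np.ndarray
    coords: np.ndarray
    kind: str
    registry: BodyJointRegistry | HandJointRegistry
    nominal_rate: float
    subject: str = ""
    handedness: str = "right"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.kind not in ("body", "hand"):
            raise ValidationError(f"unknown stream kind {self.kind!r}")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n, joints, 3)")
        if len(self.timestamps) != len(self.coords):
            raise ValidationError("timestamps and coords length mismatch")
        if len(self.timestamps) > 1 and not np.all(
            np.diff(self.timestamps) > 0
        ):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ValidationError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Covered time span assuming frames sit at 1/rate spacing."""
        if len(self) == 0:
            return 0.0
        return len(self) / self.nominal_rate

    def frame(self, i: int) -> BodyFrame | HandFrame:
        cls = BodyFrame if self.kind == "body" else HandFrame
        return cls(float(self.timestamps[i]), self.coords[i], self.registry)

    def frames(self) -> Iterator[BodyFrame | HandFrame]:
        for i in range(len(self)):
            yield self.frame(i)


def infer_rate(timestamps: np.ndarray) -> float:
    """Nominal sampling rate from timestamps, snapped to an integer when the
    estimate is within 1% of one."""
    ts = np.asarray(timestamps, dtype=float)
    if len(ts) < 2:
        raise ValidationError("cannot infer a rate from fewer than 2 frames")
    rate = (len(ts) - 1) / (ts[-1] - ts[0])
    nearest = round(rate)
    if nearest >= 1 and abs(rate - nearest) / nearest < 0.01:
        return float(nearest)
    return float(rate)
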