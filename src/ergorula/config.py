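"""Run configuration: validated defaults, overridable from YAML/JSON.

All scoring thresholds the pipeline uses (the 15 deg wrist bands, the
75/105/165 deg twist bands, the Table-4 posture bands) are fixed worksheet
constants and live in the scoring modules; the configuration covers the
genuinely open choices: registries (vertical axis, the token-19 alias),
the flexion-extension mode and neutral band, the calibration policy,
rates, the expert stride and the test level alpha.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .skeleton import BodyJointRegistry, ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    target_rate: float = 20.0          # fused grid rate, Hz
    stride: int = 10                   # expert labelling stride, fused rows
    alpha: float = 0.05                # significance level
    neutral_band_deg: float = 1.0      # shared wrist/trunk "exactly 0" band
    fe_mode: str = "literal"           # flexion-extension mode
    calibration: str | int = "first_valid"
    standing_unsupported: bool = True  # legs score 2 (study protocol)
    handedness: str = "right"
    vertical_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    alias_19: str = "03"               # body token the formula token 19 means
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fe_mode not in ("literal", "recentered"):
            raise ValidationError(f"unknown fe_mode {self.fe_mode!r}")
        if self.handedness not in ("left", "right"):
            raise ValidationError(f"unknown handedness {self.handedness!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.target_rate <= 0:
            raise ValidationError("target_rate must be positive")
        # constructing the registry validates axis norm and alias resolution
        self.body_registry()

    def body_registry(self) -> BodyJointRegistry:
        return BodyJointRegistry(
            aliases={"19": self.alias_19},
            vertical_axis=tuple(float(x) for x in self.vertical_axis),
        )

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config over the defaults; unknown keys rejected."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"{path}: unknown config key(s) {sorted(unknown)}"
        )
    if "vertical_axis" in data:
        data["vertical_axis"] = tuple(float(x) for x in data["vertical_axis"])
    return RunConfig(**data)
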