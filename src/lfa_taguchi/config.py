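"""Study configuration: validated, YAML-loadable, strict about unknown keys."""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .doe_design import DEFAULT_INPUT_LEVELS, FACTOR_CODES, FactorSpec, default_factors


class FactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    code: str
    name: str
    unit: str = ""
    levels: tuple[float, float, float]

    def to_spec(self) -> FactorSpec:
        return FactorSpec(self.code, self.name, self.unit, self.levels)


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    width: int = 120
    height: int = 400
    c_top: int = 60
    c_height: int = 20
    t_top: int = 140
    t_height: int = 20
    background_gray: int = 255


class StudyConfig(BaseModel):
    """Everything a full simulate-measure-analyze study needs.

    Defaults reproduce the reference study conditions: the four control
    factors at their screening levels, the 11-point calibration series,
    triplicate confirmation, auto pooling, and a 99% prediction CI.
    """

    model_config = ConfigDict(extra="forbid")

    factors: list[FactorConfig] = Field(
        default_factory=lambda: [
            FactorConfig(code=f.code, name=f.name, unit=f.unit, levels=f.levels)
            for f in default_factors()
        ]
    )
    input_levels: list[int] = Field(
        default_factory=lambda: list(DEFAULT_INPUT_LEVELS)
    )
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    c_target_gray: int = 125
    fixed_red: int = 255
    noise_sd: float = 2.0
    base_seed: int = 0
    pooling: Literal["auto"] | list[str] = "auto"
    alpha: float = 0.01
    sd_divisor: Literal["n", "n-1", "n-2"] = "n-1"
    confirmation_replicates: int = 3
    original_levels: tuple[int, int, int, int] = (3, 2, 2, 2)
    out_dir: str | None = None

    @field_validator("factors")
    @classmethod
    def _four_factors_in_order(cls, v: list[FactorConfig]) -> list[FactorConfig]:
        if tuple(f.code for f in v) != FACTOR_CODES:
            raise ValueError("factors must be exactly A, B, C, D in order")
        return v

    @field_validator("input_levels")
    @classmethod
    def _levels_in_range(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("input_levels must not be empty")
        if any(not 0 <= lv <= 255 for lv in v):
            raise ValueError("input levels must lie in [0, 255]")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_open_interval(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha must be in (0, 1)")
        return v

    def factor_specs(self) -> list[FactorSpec]:
        return [f.to_spec() for f in self.factors]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
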