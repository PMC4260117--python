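"""Experiment configuration: a versioned YAML schema validated with
pydantic before any simulation starts."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .errors import ConfigurationError

__all__ = ["ExperimentConfig", "load_config"]

KNOWN_SCHEMES = (
    "fixed",
    "fixed_annual",
    "ealco",
    "ed2",
    "lpj",
    "ocn",
    "isam",
    "teco",
    "daycent",
    "sdgvm",
)


class SchemeConfig(BaseModel):
    name: Literal[KNOWN_SCHEMES]  # type: ignore[valid-type]
    params: dict[str, Any] = Field(default_factory=dict)


class TurnoverConfig(BaseModel):
    u_f: float = Field(ge=0)
    u_w: float = Field(ge=0)
    u_r: float = Field(ge=0)


class ScenarioConfig(BaseModel):
    """Either a named preset (with optional field overrides) or a fully
    explicit scenario, or external CSV paths for observation tables."""

    preset: Optional[Literal["duke", "ornl"]] = None
    overrides: dict[str, Any] = Field(default_factory=dict)
    ambient_csv: Optional[str] = None
    elevated_csv: Optional[str] = None

    @field_validator("overrides")
    @classmethod
    def _no_seed_override(cls, v: dict[str, Any]) -> dict[str, Any]:
        if "seed" in v:
            raise ValueError("set the seed at the top level, not in scenario overrides")
        return v


class ExperimentConfig(BaseModel):
    schema_version: int = 1
    scheme: SchemeConfig
    turnover: TurnoverConfig
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    seed: int = 0
    outdir: str = "results/experiment"
    write_trajectories: bool = True


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config.

    Raises :class:`ConfigurationError` with pydantic's field paths on
    schema violations.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid config: {locs}") from exc
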