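"""Run configuration: mapping, inclusion rule, multipliers, rounding.

The defaults reproduce the standard 2018 analysis: representative counts
0/10/50/100, the non-sequential inclusion rule, deeper-sampling
multipliers (3, 4) and a 10,000-nematode rounding quantum on baseline
loads before the multipliers are applied.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = ["RunConfig", "MULTIPLIER_PRESETS", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


#: Named multiplier ranges for the depth-extrapolation step.
#: ``deep_sampling`` is the 3–4x deeper-scraping range; ``conservative``
#: keeps the unadjusted baseline as the lower endpoint.
MULTIPLIER_PRESETS: dict[str, tuple[float, float]] = {
    "deep_sampling": (3.0, 4.0),
    "conservative": (1.0, 4.0),
    "none": (1.0, 1.0),
}


class RunConfig(BaseModel):
    """Validated configuration for a census run."""

    model_config = ConfigDict(frozen=True)

    mapping: tuple[float, float, float, float] = (0.0, 10.0, 50.0, 100.0)
    inclusion_rule: Literal["non_sequential", "first_pass_only", "all_passes"] = (
        "non_sequential"
    )
    exclude_hosts: tuple[str, ...] = ()
    multipliers: tuple[float, float] = MULTIPLIER_PRESETS["deep_sampling"]
    multiplier_preset: str | None = None
    rounding_quantum: int = Field(default=10_000, gt=0)
    area_scale: float = Field(default=1.0, gt=0)
    seed: int | None = None

    @field_validator("mapping")
    @classmethod
    def _mapping_monotone(cls, v):
        if v[0] != 0:
            raise ValueError("mapping must send level 0 to 0")
        if not all(a < b for a, b in zip(v, v[1:])):
            raise ValueError("mapping counts must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _resolve_multipliers(self):
        if self.multiplier_preset is not None:
            try:
                preset = MULTIPLIER_PRESETS[self.multiplier_preset]
            except KeyError:
                raise ValueError(
                    f"unknown multiplier preset {self.multiplier_preset!r}; "
                    f"choose from {sorted(MULTIPLIER_PRESETS)}"
                ) from None
            object.__setattr__(self, "multipliers", preset)
        lo, hi = self.multipliers
        if not (1 <= lo <= hi):
            raise ValueError(f"need 1 <= m_lo <= m_hi, got {self.multipliers}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load and validate a YAML (or JSON) configuration file."""
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**data)
        except (yaml.YAMLError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def digest(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
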