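"""Run configuration shared by the CLI subcommands.

One YAML file can drive every subcommand; command-line flags override file
values. Threshold defaults are the guideline values the validation logic
is built around: ±25% matrix effect, 15% CV (20% near the LOQ), S/N 3/10
for LOD/LOQ, and the 8 ng/mL oral-fluid cocaine confirmation cut-off.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["Thresholds", "RunConfig", "load_config"]


class Thresholds(BaseModel):
    me_limit_pct: float = 25.0
    cv_limit_pct: float = 15.0
    cv_limit_near_loq_pct: float = 20.0
    sn_lod: float = 3.0
    sn_loq: float = 10.0
    coc_cutoff_ng_ml: float = 8.0
    near_loq_max_conc_ng_ml: float = 10.0

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v


class RunConfig(BaseModel):
    """Validated configuration for one CLI invocation."""

    seed: int = 0
    verbosity: int = 1
    thresholds: Thresholds = Field(default_factory=Thresholds)
    # simulator overrides (merged onto the packaged default truth profile)
    truth: dict[str, Any] = Field(default_factory=dict)
    design: dict[str, Any] = Field(default_factory=dict)
    metrics: list[str] | None = None
    cutoff_equivalent_ratio: float | None = None

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; a missing path yields the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
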