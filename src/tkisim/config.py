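"""Configuration loading, validation and parameter files.

Run configurations are schema-validated before any simulation starts;
unknown keys are rejected with the path to the offending block.  Parameter
files (signaling constants, inhibition table) live as YAML package data and
round-trip bit-exactly through :func:`load_yaml` / :func:`dump_yaml`.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "RunConfig",
    "PopulationBlock",
    "TrialBlock",
    "StatsBlock",
    "load_yaml",
    "dump_yaml",
    "load_signaling_config",
    "load_run_config",
    "config_hash",
]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_signaling_config() -> dict:
    """Shipped signaling constants and (drug x mutation) inhibition table."""
    ref = resources.files("tkisim.data").joinpath("signaling.yaml")
    return yaml.safe_load(ref.read_text())


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationBlock(_StrictModel):
    """Virtual-population block of a run configuration."""

    spec: str = "effect_model"  # or "li_cohort"
    n_patients: int | None = None
    overrides: dict[str, Any] = Field(default_factory=dict)


class TrialBlock(_StrictModel):
    drugs: list[str] = Field(default_factory=lambda: ["osimertinib", "gefitinib"])
    horizon_months: float = 24.0
    assessment_interval_weeks: float = 6.0
    detect_threshold_mm: float = 10.0


class StatsBlock(_StrictModel):
    n_bootstrap: int = 500
    subsample_fraction: float = 0.1
    alpha: float = 0.05
    similarity_threshold: float = 0.80


class RunConfig(_StrictModel):
    """Top-level scenario configuration."""

    scenario: str = "demo"
    master_seed: int = 0
    output_dir: str = "results"
    verbosity: str = "info"
    population: PopulationBlock = Field(default_factory=PopulationBlock)
    trial: TrialBlock = Field(default_factory=TrialBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a scenario file, reporting the offending key on error."""
    raw = load_yaml(path)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid run configuration ({path}): {locs}") from err


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, stamped onto every output."""
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
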