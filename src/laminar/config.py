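"""Validated pipeline configuration (YAML-backed, strict schema)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClassifierConfig(_Strict):
    iterations: int = Field(default=100, gt=0)
    learning_rate: float = Field(default=0.1, gt=0)


class SceneSection(_Strict):
    section_width_um: float = Field(default=1400.0, gt=0)
    rater_amplitude_um: float = Field(default=85.0, ge=0)
    rater_correlation_um: float = Field(default=150.0, gt=0)
    n_raters: int = Field(default=3, ge=1)


class PipelineConfig(_Strict):
    """Root configuration; unknown keys are rejected."""

    resolution_um_per_px: float = Field(default=0.226, gt=0)
    neighborhood_k: list[int] = Field(default=[50, 100, 250, 500, 1000])
    slices: int = Field(default=8, ge=2)
    density_k: int = Field(default=100, gt=0)
    split_fraction: float = Field(default=0.75, gt=0, lt=1)
    seed: int = 17
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    scene: SceneSection = Field(default_factory=SceneSection)

    @field_validator("neighborhood_k")
    @classmethod
    def _k_positive_sorted(cls, v):
        if not v or any(k <= 0 for k in v):
            raise ValueError("neighborhood_k must be a non-empty list of positive ints")
        return sorted(set(v))


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a YAML config; absent path yields the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    """Write the resolved configuration next to run outputs."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
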