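"""Schema-validated pipeline configuration with exact JSON round-tripping."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .acquisition import DEFAULT_OFFSETS_HZ, MTAcquisition
from .fitting import DEFAULT_BOUNDS, FitOptions
from .simulate import EffectConfig


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration files."""


class AcquisitionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    offsets_hz: tuple[float, ...] = DEFAULT_OFFSETS_HZ
    tr_s: float = 0.300
    te_s: float = 0.00418
    exc_flip_deg: float = 20.0
    mt_flip_deg: float = 540.0
    mt_pulse_shape: str = "gaussian"
    mt_pulse_duration_s: float = 0.012
    lineshape: str = "gaussian"
    n_slices: int = 16

    def build(self) -> MTAcquisition:
        return MTAcquisition(**self.model_dump())


class FitSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BOUNDS.items()}
    )
    fix_t2f: bool = True
    max_iter: int = 200
    cost_rtol: float = 1e-10
    gtol: float = 1e-10

    def build(self) -> FitOptions:
        return FitOptions(
            bounds={k: tuple(v) for k, v in self.bounds.items()},
            fix_t2f=self.fix_t2f,
            max_iter=self.max_iter,
            cost_rtol=self.cost_rtol,
            gtol=self.gtol,
        )


class ClusterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_clusters: int = 6
    fuzzifier: float = 3.0
    tol: float = 1e-6
    max_iter: int = 500
    n_init: int = 16
    seed: int = 1


class PipelineConfig(BaseModel):
    """Everything a pipeline run depends on; unknown keys are rejected.

    All randomness flows from the seeds recorded here (``effect.seed`` for
    data generation, ``cluster.seed`` for clustering restarts).
    """

    model_config = ConfigDict(extra="forbid")

    n_per_group: int = 10
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    acquisition: AcquisitionSettings = Field(default_factory=AcquisitionSettings)
    effect: EffectConfig = Field(default_factory=EffectConfig)
    fit: FitSettings = Field(default_factory=FitSettings)
    cluster: ClusterSettings = Field(default_factory=ClusterSettings)
    roi_statistic: str = "median"
    standardize: bool = True

    def reseed(self, seed: int) -> "PipelineConfig":
        """Derive a copy with all random streams re-keyed from one seed."""
        cfg = self.model_copy(deep=True)
        cfg.effect.seed = int(seed)
        cfg.cluster.seed = int(seed) + 1
        return cfg

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def to_json(self, path) -> None:
        Path(path).write_text(self.canonical_json())

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read pipeline config {path}: {exc}") from exc
        try:
            return cls.model_validate(payload)
        except Exception as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc
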