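"""Pipeline configuration: a validated JSON document.

``PipelineConfig`` is a pydantic model; ``PipelineConfig.json_schema()``
returns the JSON schema shipped with the package (also available from the
``kiwifusion schema`` CLI subcommand), and ``PipelineConfig.from_json``
loads and validates a config file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .synth import (
    AttributeTrajectory,
    ExperimentDesign,
    SensorPanel,
    SpectralModelParams,
    TrajectoryParams,
)

__all__ = ["PipelineConfig", "DesignSection", "TrajectorySection", "CarsSection", "ModelSection"]

Duty = Literal["classify", "firmness", "ssc", "ta"]
Mode = Literal["enose", "hsi", "fusion"]
Method = Literal["MWS", "SG1D", "SNV"]


class DesignSection(BaseModel):
    day_offsets: list[int] = [0, 2, 5, 8, 11, 14, 17, 20]
    fruits_per_day: int = 15


class TrajectoryAttr(BaseModel):
    start: float
    end: float
    midpoint_day: float = 6.0
    rate: float = 0.5
    residual_sd: float = 0.0


class TrajectorySection(BaseModel):
    firmness: TrajectoryAttr = TrajectoryAttr(start=7.8, end=2.6, residual_sd=0.206)
    ssc: TrajectoryAttr = TrajectoryAttr(start=7.0, end=11.44, residual_sd=0.299)
    ta: TrajectoryAttr = TrajectoryAttr(start=1.30, end=0.82, residual_sd=0.0164)


class CarsSection(BaseModel):
    n_runs: int = 100
    calibration_fraction: float = 0.8
    folds: int = 10
    max_lv: int = 20


class ModelSection(BaseModel):
    max_lv: int = 20
    folds: int = 10
    sv_grid: list[float] = [0.01, 0.1, 1.0, 10.0, 100.0]


class PipelineConfig(BaseModel):
    """Full study configuration (generation through evaluation)."""

    design: DesignSection = Field(default_factory=DesignSection)
    trajectories: TrajectorySection = Field(default_factory=TrajectorySection)
    aroma_noise_sd: float = 0.03
    enose_noise_sd: float = 0.02
    spectral_noise_sd: float = 0.005
    spectral_mismatch_sd: list[float] = [0.5, 0.45, 0.045]
    spectral_day_mismatch_sd: float = 0.75
    methods: list[Method] = ["MWS", "SG1D", "SNV"]
    cars: CarsSection = Field(default_factory=CarsSection)
    models: ModelSection = Field(default_factory=ModelSection)
    duties: list[Duty] = ["classify", "firmness", "ssc", "ta"]
    modes: list[Mode] = ["enose", "hsi", "fusion"]
    calibration_fraction: float = 0.7
    seed: int = 0
    outdir: str | None = None

    @model_validator(mode="after")
    def _check_fusion_needs_sg1d(self):
        if ("fusion" in self.modes or "hsi" in self.modes) and "SG1D" not in self.methods:
            raise ValueError(
                "hsi/fusion modes model the CARS-selected SG1D wavelengths; "
                "add 'SG1D' to methods")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration fraction must lie in (0, 1)")
        return self

    # -- converters to the generator dataclasses ---------------------------
    def experiment_design(self) -> ExperimentDesign:
        return ExperimentDesign(tuple(self.design.day_offsets),
                                self.design.fruits_per_day, seed=self.seed)

    def trajectory_params(self) -> TrajectoryParams:
        def conv(a: TrajectoryAttr) -> AttributeTrajectory:
            return AttributeTrajectory(a.start, a.end, a.midpoint_day, a.rate, a.residual_sd)
        return TrajectoryParams(conv(self.trajectories.firmness),
                                conv(self.trajectories.ssc),
                                conv(self.trajectories.ta))

    def sensor_panel(self) -> SensorPanel:
        return SensorPanel(noise_sd=self.enose_noise_sd)

    def spectral_params(self) -> SpectralModelParams:
        return SpectralModelParams(noise_sd=self.spectral_noise_sd,
                                   mismatch_sd=tuple(self.spectral_mismatch_sd),
                                   day_mismatch_sd=self.spectral_day_mismatch_sd)

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def json_schema(cls) -> dict:
        return cls.model_json_schema()

    def noise_free(self) -> "PipelineConfig":
        """Copy with every noise source zeroed (the exactness fixture)."""
        cfg = self.model_copy(deep=True)
        cfg.aroma_noise_sd = 0.0
        cfg.enose_noise_sd = 0.0
        cfg.spectral_noise_sd = 0.0
        cfg.spectral_mismatch_sd = [0.0, 0.0, 0.0]
        cfg.spectral_day_mismatch_sd = 0.0
        for attr in ("firmness", "ssc", "ta"):
            getattr(cfg.trajectories, attr).residual_sd = 0.0
        return cfg
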