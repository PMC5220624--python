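"""Structured run configuration: validation, defaults and (de)serialization.

An empty configuration file yields the default protocol: the published
compartment table, 400 N half-sinusoid compressions at 100/min with 50%
duty cycle, TPF 0.75, 40 s simulated at a 1 ms step, PLR at 90° starting
at 20 s, measurement windows 10–20 s and 30–40 s.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .forcing import (
    DEFAULT_K_LUNG,
    DEFAULT_K_MED,
    CompressionConfig,
    ForcingProtocol,
    PlrConfig,
)
from .parameters import ModelParameters

__all__ = ["RunConfig", "load_config", "save_config"]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CompressionSettings(_Base):
    amplitude: float = Field(400.0, ge=0.0, description="N")
    frequency: float = Field(100.0, gt=0.0, description="per minute")
    duty_cycle: float = Field(0.5, gt=0.0, lt=1.0)
    k_lung: float = Field(DEFAULT_K_LUNG, ge=0.0, description="mmHg/N")
    k_med: float = Field(DEFAULT_K_MED, ge=0.0, description="mmHg/N")
    force_gate_threshold: float = Field(1e-9, ge=0.0, description="N")


class PlrSettings(_Base):
    enabled: bool = True
    angle_deg: float = Field(90.0, ge=0.0, le=90.0)
    start_time: float = Field(20.0, ge=0.0, description="s")
    leg_length: float = Field(0.79, gt=0.0, description="m")
    ramp: float = Field(0.0, ge=0.0, description="s; 0 = instantaneous")


class SolverSettings(_Base):
    dt: float = Field(1e-3, gt=0.0, description="s")
    duration: float = Field(40.0, gt=0.0, description="s")
    record_every: int = Field(1, ge=1)
    method: Literal["rk4", "euler"] = "rk4"


class WindowSettings(_Base):
    before: tuple[float, float] = (10.0, 20.0)
    after: tuple[float, float] = (30.0, 40.0)


class RunConfig(_Base):
    """Fully validated configuration of one run or experiment."""

    parameters: Literal["paper-default"] | dict = "paper-default"
    tpf: float = Field(0.75, ge=0.0, le=1.0)
    compression: CompressionSettings = Field(default_factory=CompressionSettings)
    plr: PlrSettings = Field(default_factory=PlrSettings)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    windows: WindowSettings = Field(default_factory=WindowSettings)
    output_dir: str = "."
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_consistency(self) -> "RunConfig":
        period = 60.0 / self.compression.frequency
        ratio = period / self.solver.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError(
                f"dt={self.solver.dt} s must divide the compression period "
                f"{period} s within 1e-9"
            )
        for name, (a, b) in (
            ("before", self.windows.before), ("after", self.windows.after)
        ):
            if not 0.0 <= a < b:
                raise ValueError(
                    f"window '{name}' ({a}, {b}) s must be non-empty and "
                    "non-negative"
                )
        # windows may exceed a deliberately short run (e.g. a 1 s smoke
        # simulation); coverage is enforced where the window is consumed.
        return self

    # -- materialization -------------------------------------------------
    def model_parameters(self) -> ModelParameters:
        if self.parameters == "paper-default":
            return ModelParameters(tpf=self.tpf)
        d = dict(self.parameters)
        d["tpf"] = self.tpf
        return ModelParameters.from_dict(d)

    def protocol(self) -> ForcingProtocol:
        comp = CompressionConfig(
            amplitude=self.compression.amplitude,
            frequency=self.compression.frequency,
            duty_cycle=self.compression.duty_cycle,
            k_lung=self.compression.k_lung,
            k_med=self.compression.k_med,
            force_gate_threshold=self.compression.force_gate_threshold,
        )
        plr = None
        if self.plr.enabled:
            plr = PlrConfig(
                angle_deg=self.plr.angle_deg,
                start_time=self.plr.start_time,
                leg_length=self.plr.leg_length,
                ramp=self.plr.ramp,
            )
        return ForcingProtocol(
            compression=comp, plr=plr, duration=self.solver.duration
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration file.

    ``None`` or an empty file yields the defaults; unknown keys are
    rejected with a message naming the key.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=False)
    )
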