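"""Run configuration: validated YAML/JSON loading with strict keys.

A run config bundles the radiometric constants (with optional alpha/beta
overrides), the simulation grid, aggregation settings, and bookkeeping
(seed, paths, log level).  Unknown keys are rejected so typos fail loudly,
and relative humidity given percent-style (values above 1) is rejected
with a hint rather than silently rescaled.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .radiometry import RadiometricConstants
from .simulator import (
    INCUBATOR_SETTINGS,
    OBJECT_TEMPS_C,
    SimulationConfig,
)

__all__ = ["RunConfig", "load_config", "save_config"]

logger = logging.getLogger("nirtcal")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RadiometryBlock(_StrictModel):
    """Constant overrides; defaults are the printed/published values."""

    sigma: float = 5.670367e-8
    k_atm: float = 1.9
    alpha1: float = 0.006569
    alpha2: float = 0.01262
    beta1: float = -0.002276
    beta2: float = -0.00667
    h1: float = 1.5587
    h2: float = 6.939e-2
    h3: float = -2.7816e-4
    h4: float = 6.8455e-7

    def to_constants(self) -> RadiometricConstants:
        return RadiometricConstants(**self.model_dump())


def _check_rh(v: float) -> float:
    if not 0.0 <= v <= 1.0:
        hint = f"; did you mean {v / 100:g}?" if 1.0 < v <= 100.0 else ""
        raise ValueError(f"relative humidity must be a fraction in [0, 1]{hint}")
    return v


class SimulationBlock(_StrictModel):
    """The condition grid and the camera/acquisition model."""

    object_temps_c: list[float] = Field(default_factory=lambda: list(OBJECT_TEMPS_C))
    incubator_settings: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(s) for s in INCUBATOR_SETTINGS]
    )
    distance: float = 0.4
    eps_obj: float = 0.97
    eps_rs: float = 0.95
    gain: float = 1.08
    offset: float = 0.3
    drift_amplitude: float = 2.0
    drift_period_s: float = 600.0
    nuc_interval_s: float = 180.0
    nuc_residual_fraction: float = 0.3
    netd_c: float = 0.05
    thermistor_noise_c: float = 0.01
    frame_shape: tuple[int, int] = (80, 64)
    rois: dict[str, tuple[int, int, int, int]] | None = None
    n_frames: int = 1200
    frame_rate_hz: float = 1.0

    @field_validator("incubator_settings")
    @classmethod
    def _validate_settings(cls, v):
        for t, rh in v:
            _check_rh(rh)
        return v

    def base_config(self, constants: RadiometricConstants, seed: int) -> SimulationConfig:
        kwargs = dict(
            distance=self.distance,
            eps_obj=self.eps_obj,
            eps_rs=self.eps_rs,
            gain=self.gain,
            offset=self.offset,
            drift_amplitude=self.drift_amplitude,
            drift_period_s=self.drift_period_s,
            nuc_interval_s=self.nuc_interval_s,
            nuc_residual_fraction=self.nuc_residual_fraction,
            netd_c=self.netd_c,
            thermistor_noise_c=self.thermistor_noise_c,
            frame_shape=tuple(self.frame_shape),
            n_frames=self.n_frames,
            frame_rate_hz=self.frame_rate_hz,
            seed=seed,
            constants=constants,
        )
        if self.rois is not None:
            kwargs["rois"] = {k: tuple(v) for k, v in self.rois.items()}
        return SimulationConfig(**kwargs)

    def conditions(self) -> list[tuple[float, float, float]]:
        return [
            (t_obj, t_incu, rh)
            for t_obj in self.object_temps_c
            for (t_incu, rh) in self.incubator_settings
        ]


class RunConfig(_StrictModel):
    """Top-level validated configuration for a pipeline run."""

    radiometry: RadiometryBlock = Field(default_factory=RadiometryBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    trim_fraction: float = 0.10
    calibration_path: str | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("trim_fraction")
    @classmethod
    def _validate_trim(cls, v):
        if not 0.0 <= v < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        return v

    @field_validator("log_level")
    @classmethod
    def _validate_log_level(cls, v):
        if v.upper() not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
            raise ValueError(f"unknown log level {v!r}")
        return v.upper()

    def constants(self) -> RadiometricConstants:
        return self.radiometry.to_constants()


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run config; defaults fill gaps.

    The effective (post-default) configuration is echoed to the package
    logger at DEBUG level for reproducibility.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    cfg = RunConfig.model_validate(raw)
    logging.getLogger("nirtcal").debug(
        "effective config: %s", json.dumps(cfg.model_dump(), default=list)
    )
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back out (YAML or JSON by extension); round-trips."""
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
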