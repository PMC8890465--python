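"""Synthetic-data generator: an uncooled thermal camera viewing a blackbody
furnace and a passive reference blackbody inside a convective incubator.

Forward model, per frame and per scene pixel:

1. Scene radiance from the radiance chain
   W_tot = eps * tau * W_surf + (1 - eps) * tau * W_ref + (1 - tau) * W_atm,
   with W_ref = W_atm = W_amb = sigma * (T_incu + 273.15)^4 (uniform air
   temperature).  The passive reference blackbody equilibrates with the
   incubator air, so its surface temperature is T_incu and its scene
   radiance is exactly W_amb.
2. Detector-chain (internal) errors:
   W_det = gain * W_tot + offset + drift(t) + noise, where drift is a slow
   additive radiance sinusoid partially reset at each non-uniformity
   correction (NUC, mechanical-shutter) event — producing the sawtooth
   fluctuation characteristic of microbolometer thermal drift — and the
   per-pixel noise standard deviation corresponds to the camera's NETD in
   Kelvin at the local scene temperature.
3. Frames are stored as apparent temperature (W_det / sigma)^(1/4) - 273.15,
   the emissivity-1.0 camera-export convention.

The accompanying thermistor log reports the reference body's internal
temperature (= incubator air temperature) with small sensor noise.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning (per condition), so grids are reproducible piecewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .frames import FrameSequence, rect_mask
from .radiometry import (
    CELSIUS_ZERO,
    DEFAULT_CONSTANTS,
    EnvironmentState,
    RadiometricConstants,
    celsius_to_radiance,
)

__all__ = [
    "SimulationConfig",
    "ConditionData",
    "GridCondition",
    "CAMERA_PRESETS",
    "paper_grid",
    "two_point_subset",
    "simulate_condition",
    "simulate_grid",
]

# Default ROI rectangles (half-open row/col bounds) on the default 80 x 64
# sensor: two 16 x 16 trace areas, object left, reference right.
_DEFAULT_ROIS = {
    "object": (32, 48, 8, 24),
    "reference": (32, 48, 40, 56),
}


@dataclass(frozen=True)
class SimulationConfig:
    """One measurement condition of the incubator accuracy protocol.

    Scene defaults reproduce the study conditions: a furnace near body
    temperature inside an incubator at 30-39 degC and 50-90% relative
    humidity, captured at 1 Hz for 20 minutes (1200 frames).  Camera
    defaults emulate a typical uncooled microbolometer: an 8% gain error
    on the detected-radiance channel (the magnitude implied by recalibration
    slopes fitted to real A35-class cameras), a small radiance offset, slow
    FPA thermal drift partially reset by periodic NUC shutter events, and
    0.05 degC NETD pixel noise.
    """

    # scene / environment
    t_set_obj: float = 37.0       # furnace set temperature, degC
    t_set_incu: float = 33.0      # incubator air temperature, degC
    rh_set_incu: float = 0.6      # relative humidity, fraction
    distance: float = 0.4         # camera-to-target path, m
    eps_obj: float = 0.97
    eps_rs: float = 0.95
    # detector-chain error terms
    gain: float = 1.08            # multiplicative error on detected radiance
    offset: float = 0.3           # additive radiance bias, W m^-2
    drift_amplitude: float = 2.0  # FPA drift sinusoid amplitude, W m^-2
    drift_period_s: float = 600.0
    nuc_interval_s: float = 180.0
    nuc_residual_fraction: float = 0.3  # drift surviving a shutter event
    netd_c: float = 0.05          # per-pixel noise SD, degC
    thermistor_noise_c: float = 0.01
    # acquisition
    frame_shape: tuple[int, int] = (80, 64)
    rois: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_ROIS)
    )
    n_frames: int = 1200
    frame_rate_hz: float = 1.0
    seed: int = 0
    constants: RadiometricConstants = DEFAULT_CONSTANTS

    def validate(self) -> None:
        if not -25.0 <= self.t_set_obj <= 100.0 or not -25.0 <= self.t_set_incu <= 100.0:
            raise ValueError("set temperatures outside camera operating range")
        if not 0.0 <= self.rh_set_incu <= 1.0:
            raise ValueError("rh_set_incu must be a fraction in [0, 1]")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if not 0 < self.eps_obj <= 1 or not 0 < self.eps_rs <= 1:
            raise ValueError("emissivities must be in (0, 1]")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.drift_amplitude < 0 or self.netd_c < 0 or self.thermistor_noise_c < 0:
            raise ValueError("noise/drift magnitudes must be non-negative")
        if self.drift_period_s <= 0 or self.nuc_interval_s <= 0:
            raise ValueError("drift and NUC periods must be positive")
        if not 0.0 <= self.nuc_residual_fraction <= 1.0:
            raise ValueError("nuc_residual_fraction must be in [0, 1]")
        if self.n_frames < 1 or self.frame_rate_hz <= 0:
            raise ValueError("need n_frames >= 1 and a positive frame rate")
        rows, cols = self.frame_shape
        if rows < 1 or cols < 1:
            raise ValueError("frame_shape must be positive")
        if not {"object", "reference"} <= set(self.rois):
            raise ValueError('rois must define "object" and "reference"')
        for name, rect in self.rois.items():
            rect_mask(self.frame_shape, rect)  # bounds check

    def environment(self) -> EnvironmentState:
        return EnvironmentState(
            t_atm_c=self.t_set_incu, rh=self.rh_set_incu, distance_m=self.distance
        )

    def clean(self) -> "SimulationConfig":
        """Copy with every detector-chain error term switched off."""
        return replace(
            self,
            gain=1.0,
            offset=0.0,
            drift_amplitude=0.0,
            netd_c=0.0,
            thermistor_noise_c=0.0,
        )


# Per-camera detector-chain presets.  Gains are the reciprocals of
# recalibration slopes observed on real cameras of each class (two A35
# units and one Lepton 3.5); the power-saving Lepton is given stronger
# drift, matching its poorer uncorrected stability.
CAMERA_PRESETS: dict[str, dict[str, float]] = {
    "IRT-1": {"gain": 1 / 0.924892, "offset": 0.3, "drift_amplitude": 2.0},
    "IRT-2": {"gain": 1 / 0.9805749, "offset": 0.2, "drift_amplitude": 2.0},
    "IRT-3": {"gain": 1 / 1.1669497, "offset": 0.5, "drift_amplitude": 3.0},
}


class ConditionData(NamedTuple):
    """Output of one simulated condition."""

    frames: FrameSequence
    thermistor: pd.DataFrame  # columns time_s, temperature_C
    truth: dict               # t_set_obj, t_set_incu, rh, tau, w_amb, ...


class GridCondition(NamedTuple):
    label: str
    config: SimulationConfig
    data: ConditionData


def _drift_series(times: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Sinusoidal FPA drift with partial resets at NUC shutter events.

    Between events the drift follows the increments of
    A * sin(2*pi*t / period); at each NUC event (every nuc_interval_s)
    the accumulated level is attenuated to ``nuc_residual_fraction`` of
    itself and then re-grows — a sawtooth-modulated slow oscillation.
    """
    if cfg.drift_amplitude == 0:
        return np.zeros_like(times)
    drift = np.empty_like(times)
    level = 0.0
    prev_raw = 0.0
    next_nuc = cfg.nuc_interval_s
    for i, t in enumerate(times):
        raw = cfg.drift_amplitude * math.sin(2 * math.pi * t / cfg.drift_period_s)
        level += raw - prev_raw
        prev_raw = raw
        while t >= next_nuc:
            level *= cfg.nuc_residual_fraction
            next_nuc += cfg.nuc_interval_s
        drift[i] = level
    return drift


def _scene_radiance(w_surf: float, eps: float, tau: float, w_amb: float) -> float:
    """Radiance chain: emitted + reflected-ambient + atmospheric terms."""
    return eps * tau * w_surf + (1.0 - eps) * tau * w_amb + (1.0 - tau) * w_amb


def simulate_condition(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ConditionData:
    """Simulate one condition: frames, thermistor log, and ground truth."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    c = cfg.constants
    env = cfg.environment()
    tau = env.transmittance(c)
    w_amb = env.ambient_radiance(c)
    w_obj_true = celsius_to_radiance(cfg.t_set_obj, c)

    # Scene radiances (constant over the condition; the furnace is stable
    # to millikelvin and the incubator holds a steady state).
    w_scene = {
        "object": _scene_radiance(w_obj_true, cfg.eps_obj, tau, w_amb),
        # reference surface temperature = incubator air (passive
        # equilibration); algebraically this collapses to w_amb exactly.
        "reference": _scene_radiance(w_amb, cfg.eps_rs, tau, w_amb),
    }

    times = np.arange(cfg.n_frames) / cfg.frame_rate_hz
    drift = _drift_series(times, cfg)

    # Background pixels view the far incubator wall at air temperature.
    w_det_bg = cfg.gain * w_amb + cfg.offset + drift
    frames = np.empty((cfg.n_frames, *cfg.frame_shape), dtype=float)
    frames[:] = ((w_det_bg / c.sigma) ** 0.25 - CELSIUS_ZERO)[:, None, None]

    masks = {name: rect_mask(cfg.frame_shape, rect) for name, rect in cfg.rois.items()}
    for name, mask in masks.items():
        w_tot = w_scene[name]
        w_det = cfg.gain * w_tot + cfg.offset + drift[:, None]
        if cfg.netd_c > 0:
            # NETD in kelvin -> radiance noise via dW/dT at the scene's
            # apparent temperature.
            t_app_k = (w_tot / c.sigma) ** 0.25
            sd_w = cfg.netd_c * 4.0 * c.sigma * t_app_k**3
            w_det = w_det + rng.normal(0.0, sd_w, size=(cfg.n_frames, int(mask.sum())))
        else:
            w_det = np.broadcast_to(w_det, (cfg.n_frames, int(mask.sum())))
        frames[:, mask] = (w_det / c.sigma) ** 0.25 - CELSIUS_ZERO

    seq = FrameSequence(frames=frames, timestamps=times, rois=masks)

    t_thermistor = np.full(cfg.n_frames, cfg.t_set_incu)
    if cfg.thermistor_noise_c > 0:
        t_thermistor = t_thermistor + rng.normal(
            0.0, cfg.thermistor_noise_c, size=cfg.n_frames
        )
    thermistor = pd.DataFrame({"time_s": times, "temperature_C": t_thermistor})

    truth = {
        "t_set_obj": cfg.t_set_obj,
        "t_set_incu": cfg.t_set_incu,
        "rh_set_incu": cfg.rh_set_incu,
        "distance": cfg.distance,
        "eps_obj": cfg.eps_obj,
        "eps_rs": cfg.eps_rs,
        "tau_atm": float(tau),
        "w_amb": float(w_amb),
        "w_obj_true": float(w_obj_true),
        "gain": cfg.gain,
        "offset": cfg.offset,
        "seed": cfg.seed,
    }
    return ConditionData(frames=seq, thermistor=thermistor, truth=truth)


# ------------------------------------------------------------------- grid

# The 24-condition accuracy protocol: four furnace set temperatures in the
# neonatal normothermic range crossed with six incubator settings spanning
# the 30-39 degC / 50-90% RH clinical envelope (a low- and a high-humidity
# setting at each of three air temperatures).
OBJECT_TEMPS_C = (35.0, 36.0, 37.0, 38.0)
INCUBATOR_SETTINGS = (
    (30.0, 0.5),
    (30.0, 0.9),
    (34.0, 0.5),
    (34.0, 0.8),
    (39.0, 0.5),
    (39.0, 0.8),
)


def paper_grid() -> list[tuple[float, float, float]]:
    """The 24 (t_set_obj, t_set_incu, rh) study conditions."""
    return [
        (t_obj, t_incu, rh)
        for t_obj in OBJECT_TEMPS_C
        for (t_incu, rh) in INCUBATOR_SETTINGS
    ]


def two_point_subset(
    conditions: list[tuple[float, float, float]],
) -> list[tuple[float, float, float]]:
    """The two calibration conditions with the largest object-incubator
    temperature differences of either sign (e.g. incubator 30 / object 38,
    and incubator 39 / object 35).  Ties broken by list order."""
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    hi = max(conditions, key=lambda c: c[0] - c[1])
    lo = min(conditions, key=lambda c: c[0] - c[1])
    if hi == lo:
        raise ValueError("conditions are degenerate: no temperature spread")
    return [hi, lo]


def condition_label(t_obj: float, t_incu: float, rh: float) -> str:
    return f"obj{t_obj:g}_incu{t_incu:g}_rh{round(rh * 100):d}"


def simulate_grid(
    base_cfg: SimulationConfig,
    conditions: list[tuple[float, float, float]] | None = None,
    base_seed: int | None = None,
) -> list[GridCondition]:
    """Simulate a grid of conditions with per-condition derived seeds.

    Each condition draws its generator from a child of one
    ``SeedSequence``, so the grid is deterministic given the base seed and
    reproducible condition by condition.
    """
    if conditions is None:
        conditions = paper_grid()
    if not conditions:
        return []
    labels = [condition_label(*cond) for cond in conditions]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate condition labels: {dupes}")
    seed = base_seed if base_seed is not None else base_cfg.seed
    children = np.random.SeedSequence(seed).spawn(len(conditions))
    out: list[GridCondition] = []
    for (t_obj, t_incu, rh), label, child in zip(conditions, labels, children):
        cond_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(
            base_cfg,
            t_set_obj=t_obj,
            t_set_incu=t_incu,
            rh_set_incu=rh,
            seed=cond_seed,
        )
        out.append(GridCondition(label=label, config=cfg, data=simulate_condition(cfg)))
    return out
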