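"""Radiometric conversions and the atmospheric transmittance model.

Total-radiance (Stefan–Boltzmann) radiometry: a surface at absolute
temperature T emits W = sigma * T**4, and an apparent temperature read off a
thermal camera with emissivity set to 1.0 encodes the total detected
radiance through the same law.  Atmospheric attenuation over the short
camera-to-target path inside an incubator is modelled with the two-term
exponential transmittance formula used by FLIR analysis tools, driven by a
water-vapour content term that is linear in relative humidity.

All public functions accept scalars or numpy arrays and operate
elementwise.  Temperatures are Kelvin internally; ``*_celsius`` helpers
convert at the boundary (incubator and body temperatures are conventionally
quoted in Celsius).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

CELSIUS_ZERO = 273.15

__all__ = [
    "CELSIUS_ZERO",
    "RadiometricConstants",
    "DEFAULT_CONSTANTS",
    "EnvironmentState",
    "temperature_to_radiance",
    "radiance_to_temperature",
    "celsius_to_radiance",
    "radiance_to_celsius",
    "water_vapour_content",
    "atmospheric_transmittance",
]


@dataclass(frozen=True)
class RadiometricConstants:
    """Physical and atmospheric-model constants.

    Attributes
    ----------
    sigma : float
        Stefan–Boltzmann constant, W m^-2 K^-4.
    k_atm : float
        Scaling factor for atmospheric damping (dimensionless) in the
        two-term transmittance mixture.
    alpha1, alpha2 : float
        Attenuation factors for the atmosphere without water vapour,
        m^-1/2.
    beta1, beta2 : float
        Attenuation factors for water vapour.
    h1, h2, h3, h4 : float
        Polynomial coefficients of the water-vapour-content model
        (argument in degrees Celsius).

    The alpha/beta defaults are the published FLIR research values; they
    are configurable because vendor tools ship them in firmware rather
    than print them.
    """

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

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"constant {f.name!r} must be finite, got {v!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def replace(self, **overrides: float) -> "RadiometricConstants":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(overrides)
        return RadiometricConstants(**values)


DEFAULT_CONSTANTS = RadiometricConstants()


def _as_float(x):
    a = np.asarray(x, dtype=float)
    return a


def _maybe_scalar(a: np.ndarray):
    return float(a) if a.ndim == 0 else a


def temperature_to_radiance(t_kelvin, constants: RadiometricConstants = DEFAULT_CONSTANTS):
    """Blackbody exitance W = sigma * T^4 for absolute temperature T (K)."""
    t = _as_float(t_kelvin)
    if np.any(t <= 0):
        raise ValueError("absolute temperature must be positive (Kelvin)")
    return _maybe_scalar(constants.sigma * t**4)


def radiance_to_temperature(w, constants: RadiometricConstants = DEFAULT_CONSTANTS):
    """Inverse Stefan–Boltzmann: T = (W / sigma)^(1/4), Kelvin."""
    wa = _as_float(w)
    if np.any(wa <= 0):
        raise ValueError("radiance must be positive")
    return _maybe_scalar((wa / constants.sigma) ** 0.25)


def celsius_to_radiance(t_celsius, constants: RadiometricConstants = DEFAULT_CONSTANTS):
    """Radiance of a blackbody at a Celsius temperature."""
    return temperature_to_radiance(_as_float(t_celsius) + CELSIUS_ZERO, constants)


def radiance_to_celsius(w, constants: RadiometricConstants = DEFAULT_CONSTANTS):
    """Blackbody-equivalent temperature of a radiance, degrees Celsius."""
    return _maybe_scalar(_as_float(radiance_to_temperature(w, constants)) - CELSIUS_ZERO)


def water_vapour_content(rh, t_atm_c, constants: RadiometricConstants = DEFAULT_CONSTANTS):
    """Water-vapour content omega of the air path.

    Parameters
    ----------
    rh : float
        Relative humidity as a fraction in [0, 1].  Percent-style inputs
        (values above 1) are rejected rather than silently rescaled.
    t_atm_c : float
        Air temperature, degrees Celsius.

    Returns
    -------
    float
        omega = rh * exp(h1 + h2*T + h3*T^2 + h4*T^3); dimensionless,
        non-negative, exactly linear in ``rh``.
    """
    rh_a = _as_float(rh)
    if np.any(rh_a < 0) or np.any(rh_a > 1):
        raise ValueError(
            "relative humidity must be a fraction in [0, 1] "
            "(e.g. pass 0.5 for 50%, not 50)"
        )
    t = _as_float(t_atm_c)
    c = constants
    poly = c.h1 + c.h2 * t + c.h3 * t**2 + c.h4 * t**3
    return _maybe_scalar(rh_a * np.exp(poly))


def atmospheric_transmittance(
    distance_m,
    omega,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
):
    """Atmospheric transmittance tau over a path of length d.

    tau(d, omega) = K_atm * exp(-sqrt(d) * (alpha1 + beta1*sqrt(omega)))
                  + (1 - K_atm) * exp(-sqrt(d) * (alpha2 + beta2*sqrt(omega)))

    Exactly 1 at d = 0.  Results are required to lie in (0, 1]; values
    marginally above 1 (numerical noise up to 1e-4) are clamped, anything
    larger indicates inconsistent alpha/beta constants and raises.
    """
    d = _as_float(distance_m)
    om = _as_float(omega)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if np.any(om < 0):
        raise ValueError("water-vapour content must be non-negative")
    c = constants
    sqrt_d = np.sqrt(d)
    sqrt_om = np.sqrt(om)
    tau = c.k_atm * np.exp(-sqrt_d * (c.alpha1 + c.beta1 * sqrt_om)) + (
        1.0 - c.k_atm
    ) * np.exp(-sqrt_d * (c.alpha2 + c.beta2 * sqrt_om))
    tau = np.where(d == 0, 1.0, tau)
    if np.any(tau > 1.0 + 1e-4):
        raise ValueError(
            "transmittance exceeds 1 beyond numerical tolerance; "
            "check alpha/beta attenuation constants"
        )
    if np.any(tau <= 0):
        raise ValueError("transmittance must be positive; check constants")
    tau = np.minimum(tau, 1.0)
    return _maybe_scalar(tau)


@dataclass(frozen=True)
class EnvironmentState:
    """Steady-state radiative environment inside a convective incubator.

    The incubator maintains a uniform air temperature, so the reflected
    ambient radiance and the atmospheric emission are both taken equal to
    the blackbody radiance at the air temperature (W_amb = W_atm).

    Attributes
    ----------
    t_atm_c : float
        Incubator air temperature, degrees Celsius.
    rh : float
        Relative humidity, fraction in [0, 1].
    distance_m : float
        Camera-to-target path length, metres.
    """

    t_atm_c: float
    rh: float
    distance_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(
                "relative humidity must be a fraction in [0, 1] "
                "(e.g. 0.5 for 50%)"
            )
        if self.distance_m < 0:
            raise ValueError("distance must be non-negative")
        if not -40.0 < self.t_atm_c < 120.0:
            raise ValueError("air temperature outside plausible operating range")

    def ambient_radiance(self, constants: RadiometricConstants = DEFAULT_CONSTANTS) -> float:
        """W_amb = W_atm: blackbody radiance at the incubator air temperature."""
        return celsius_to_radiance(self.t_atm_c, constants)

    def water_vapour(self, constants: RadiometricConstants = DEFAULT_CONSTANTS) -> float:
        return water_vapour_content(self.rh, self.t_atm_c, constants)

    def transmittance(self, constants: RadiometricConstants = DEFAULT_CONSTANTS) -> float:
        """Per-condition tau from the condition's humidity, temperature and path."""
        return atmospheric_transmittance(
            self.distance_m, self.water_vapour(constants), constants
        )
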