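"""Radiance-domain correction equations and per-camera regression calibration.

Four estimators of the true object radiance from detected radiances:

* ``conventional_correction`` — compensates external factors only
  (emissivity, reflected ambient radiance, atmospheric transmittance):
  W_obj = (W_det1 - W_amb) / (eps_obj * tau) + W_amb.
* ``full_reference_correction`` — subtracts the same-frame estimate of a
  passive in-scene reference blackbody and re-anchors on its thermistor
  reading, cancelling detector-chain errors (thermal drift of the focal
  plane array) common to both regions of interest.
* ``reference_correction`` — the steady-state form of the above: inside a
  convective incubator the reference equilibrates with the air, so
  W_amb can be replaced by W_det2 and the reference's own correction term
  vanishes: W_COR1 = (W_det1 - W_det2) / (eps_obj * tau) + W_TMT-rs.
* ``linear_correction`` — the reference correction with a per-camera
  affine recalibration of the radiance-difference channel:
  W_COR2 = a * (W_det1 - W_det2) / (eps_obj * tau) + W_TMT-rs + b.

``fit_linear_coefficients`` estimates (a, b) by ordinary least squares of
y = W_true - W_TMT-rs on the difference-channel predictor, one point per
calibration condition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .radiometry import DEFAULT_CONSTANTS, RadiometricConstants, radiance_to_celsius

__all__ = [
    "CorrectionInputs",
    "CorrectionResult",
    "CameraCalibration",
    "conventional_correction",
    "reference_correction",
    "full_reference_correction",
    "linear_correction",
    "fit_linear_coefficients",
]


@dataclass(frozen=True)
class CorrectionInputs:
    """Radiances and scene parameters entering the correction equations.

    All radiances are W m^-2; scalars or equal-shaped arrays (e.g. a
    per-second time series).

    Attributes
    ----------
    w_det1 : detected radiance of the object region of interest.
    w_det2 : detected radiance of the reference-source region of interest.
    w_amb : ambient (= atmospheric) radiance from the incubator air
        temperature; only the conventional and full-reference forms use it.
    w_tmt_rs : radiance of the reference blackbody computed from its
        internal thermistor temperature.
    eps_obj : object emissivity (0.97: blackbody furnace default).
    eps_rs : reference-source emissivity (0.95: blackbody wrapped in
        high-emissivity tape).
    tau_atm : atmospheric transmittance for the condition.
    """

    w_det1: object
    w_det2: object
    w_amb: object
    w_tmt_rs: object
    eps_obj: float = 0.97
    eps_rs: float = 0.95
    tau_atm: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eps_obj <= 1.0:
            raise ValueError("eps_obj must be in (0, 1]")
        if not 0.0 < self.eps_rs <= 1.0:
            raise ValueError("eps_rs must be in (0, 1]")
        if not 0.0 < self.tau_atm <= 1.0:
            raise ValueError("tau_atm must be in (0, 1]")


class CorrectionResult(NamedTuple):
    """Corrected radiance with its blackbody-equivalent temperature."""

    radiance: object  # W m^-2
    temperature_c: object


def _result(w, constants: RadiometricConstants) -> CorrectionResult:
    # A corrected radiance can go non-positive for inconsistent inputs
    # (e.g. an object far colder than the reference); keep the radiance
    # and report NaN for the unphysical temperature instead of raising.
    wa = np.asarray(w, dtype=float)
    with np.errstate(invalid="ignore"):
        t = np.where(wa > 0, (wa / constants.sigma) ** 0.25 - 273.15, np.nan)
    if wa.ndim == 0:
        return CorrectionResult(float(wa), float(t))
    return CorrectionResult(wa, t)


def conventional_correction(
    inputs: CorrectionInputs,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> CorrectionResult:
    """External-factor correction: emissivity, reflection, transmittance.

    W_obj = (W_det1 - W_amb) / (eps_obj * tau_atm) + W_amb.
    """
    denom = inputs.eps_obj * inputs.tau_atm
    if denom == 0:
        raise ValueError("degenerate configuration: eps_obj * tau_atm == 0")
    w1 = np.asarray(inputs.w_det1, dtype=float)
    w_obj = (w1 - inputs.w_amb) / denom + inputs.w_amb
    return _result(w_obj, constants)


def reference_correction(
    inputs: CorrectionInputs,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> CorrectionResult:
    """Steady-state in-scene reference correction.

    W_COR1 = (W_det1 - W_det2) / (eps_obj * tau_atm) + W_TMT-rs.
    Detector-chain terms common to both regions (drift, offset) cancel in
    the difference.
    """
    denom = inputs.eps_obj * inputs.tau_atm
    if denom == 0:
        raise ValueError("degenerate configuration: eps_obj * tau_atm == 0")
    w1 = np.asarray(inputs.w_det1, dtype=float)
    w_cor1 = (w1 - inputs.w_det2) / denom + inputs.w_tmt_rs
    return _result(w_cor1, constants)


def full_reference_correction(
    inputs: CorrectionInputs,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> CorrectionResult:
    """Reference correction without the steady-state assumption.

    W_COR1 = (W_det1 - W_amb)/(eps_obj*tau) - (W_det2 - W_amb)/(eps_rs*tau)
             + W_TMT-rs,
    which reduces exactly to :func:`reference_correction` when
    W_amb = W_det2.
    """
    d_obj = inputs.eps_obj * inputs.tau_atm
    d_rs = inputs.eps_rs * inputs.tau_atm
    if d_obj == 0 or d_rs == 0:
        raise ValueError("degenerate configuration: emissivity * tau == 0")
    w1 = np.asarray(inputs.w_det1, dtype=float)
    w_cor1 = (
        (w1 - inputs.w_amb) / d_obj
        - (np.asarray(inputs.w_det2, dtype=float) - inputs.w_amb) / d_rs
        + inputs.w_tmt_rs
    )
    return _result(w_cor1, constants)


@dataclass(frozen=True)
class CameraCalibration:
    """Per-camera affine recalibration of the radiance-difference channel.

    ``a`` multiplies the predictor x = (W_det1 - W_det2)/(eps_obj*tau);
    ``b`` (W m^-2) is the intercept.  ``r_squared`` is the coefficient of
    determination of the calibration fit and ``n_conditions`` the number
    of calibration conditions it pooled.
    """

    camera_id: str
    a: float
    b: float
    r_squared: float
    n_conditions: int
    fit_timestamp: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or not np.isfinite(self.b):
            raise ValueError("calibration coefficients must be finite")
        if self.a <= 0:
            raise ValueError("calibration slope must be positive")
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_conditions < 2:
            raise ValueError("calibration needs at least 2 conditions")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CameraCalibration":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


IDENTITY_CALIBRATION = CameraCalibration(
    camera_id="identity", a=1.0, b=0.0, r_squared=1.0, n_conditions=2
)


def linear_correction(
    inputs: CorrectionInputs,
    cal: CameraCalibration,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> CorrectionResult:
    """Regression-calibrated reference correction.

    W_COR2 = a * (W_det1 - W_det2)/(eps_obj*tau) + W_TMT-rs + b.
    With (a, b) = (1, 0) this is exactly :func:`reference_correction`.
    """
    denom = inputs.eps_obj * inputs.tau_atm
    if denom == 0:
        raise ValueError("degenerate configuration: eps_obj * tau_atm == 0")
    w1 = np.asarray(inputs.w_det1, dtype=float)
    x = (w1 - inputs.w_det2) / denom
    w_cor2 = cal.a * x + inputs.w_tmt_rs + cal.b
    return _result(w_cor2, constants)


def fit_linear_coefficients(
    predictor,
    w_tmt_rs,
    w_true,
    camera_id: str = "camera",
    fit_timestamp: str | None = None,
) -> CameraCalibration:
    """Fit the linear-correction coefficients by ordinary least squares.

    Parameters
    ----------
    predictor : array-like, one value per calibration condition
        x = (W_det1 - W_det2) / (eps_obj * tau), W m^-2, typically the
        per-condition average of the per-second channel.
    w_tmt_rs : array-like
        Per-condition average thermistor radiance of the reference source.
    w_true : array-like
        True object radiance per condition, computed from the object's
        set temperature (the furnace set point serves as ground truth).

    Returns
    -------
    CameraCalibration
        OLS slope ``a`` and intercept ``b`` of y = W_true - W_TMT-rs on x,
        with the fit's R^2.  With exactly two distinct conditions the line
        interpolates both points and R^2 = 1.

    Raises
    ------
    ValueError
        Fewer than two conditions, or all predictor values identical
        (rank-deficient design).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(w_true, dtype=float) - np.asarray(w_tmt_rs, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("predictor and responses must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("need at least 2 calibration conditions")
    if np.ptp(x) == 0:
        raise ValueError("all predictor values identical: rank-deficient design")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue) ** 2
    return CameraCalibration(
        camera_id=camera_id,
        a=float(fit.slope),
        b=float(fit.intercept),
        r_squared=min(r2, 1.0),
        n_conditions=int(x.size),
        fit_timestamp=fit_timestamp,
    )
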