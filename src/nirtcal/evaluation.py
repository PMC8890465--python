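"""Accuracy evaluation: MAE/SD per condition, clinical accuracy gates, and
chi-square comparison of accuracy proportions between correction equations.

Gates follow the clinical-thermometry standards for skin thermometers and
fever-screening thermographs: high accuracy is a per-condition mean
absolute error (MAE) within 0.3 degC of the object's set temperature, and
high stability is a standard deviation of the per-second absolute errors
below 0.1 degC.  Accuracy of an equation over a study is the percentage of
conditions meeting the gate, and equations are compared with a Pearson
chi-square test on the 2x2 within/outside table (df = 1, no continuity
correction, two-tailed).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correction import (
    CameraCalibration,
    CorrectionInputs,
    conventional_correction,
    fit_linear_coefficients,
    linear_correction,
    reference_correction,
)
from .frames import (
    DEFAULT_TRIM_FRACTION,
    aggregate_condition,
    apparent_temperature_to_radiance_series,
    extract_roi_series,
)
from .radiometry import DEFAULT_CONSTANTS, RadiometricConstants, celsius_to_radiance
from .simulator import ConditionData, GridCondition, two_point_subset

__all__ = [
    "ACCURACY_GATE_C",
    "STABILITY_GATE_C",
    "EQUATIONS",
    "ConditionResult",
    "mae",
    "accuracy_percentage",
    "chi_square_accuracy",
    "condition_channels",
    "correct_condition",
    "calibration_points",
    "fit_grid_calibration",
    "evaluate_pipeline",
]

ACCURACY_GATE_C = 0.3   # ASTM-style skin-thermometer accuracy bound, degC
STABILITY_GATE_C = 0.1  # IEC-style fever-screening stability bound, degC

#: Correction-equation identifiers: eq3 conventional, eq8 steady-state
#: reference, eq9 regression-calibrated (all-condition fit), eq10
#: regression-calibrated (two-condition fit).
EQUATIONS = ("eq3", "eq8", "eq9", "eq10")


@dataclass(frozen=True)
class ConditionResult:
    """Per-condition, per-equation accuracy summary.

    ``mae``/``sd`` are over the per-second absolute errors; ``sd_estimates``
    is the within-condition fluctuation of the corrected series itself;
    ``within_tolerance`` is the primary MAE-based accuracy flag and
    ``within_point`` the flag on the per-condition point estimate.
    """

    condition_label: str
    equation_id: str
    mae: float
    sd: float
    sd_estimates: float
    mean_estimate: float
    within_tolerance: bool
    stable: bool
    within_point: bool

    def __post_init__(self) -> None:
        if self.mae < 0 or self.sd < 0:
            raise ValueError("mae and sd must be non-negative")


def mae(estimates, truth: float) -> float:
    """Mean absolute error of a per-second series against the set temperature."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("cannot compute MAE of an empty series")
    return float(np.mean(np.abs(e - truth)))


def accuracy_percentage(within_flags) -> float:
    """Percentage of conditions meeting the accuracy gate, one decimal."""
    f = np.asarray(within_flags, dtype=bool)
    if f.size == 0:
        raise ValueError("need at least one condition")
    return float(round(100.0 * float(f.mean()), 1))


def chi_square_accuracy(
    n_within_1: int, n_total_1: int, n_within_2: int, n_total_2: int
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 within/outside-tolerance table.

    df = 1, no Yates continuity correction, two-tailed p from the
    chi-square distribution.
    """
    for w, t in ((n_within_1, n_total_1), (n_within_2, n_total_2)):
        if t <= 0 or not 0 <= w <= t:
            raise ValueError("counts must satisfy 0 <= within <= total, total > 0")
    table = np.array(
        [
            [n_within_1, n_total_1 - n_within_1],
            [n_within_2, n_total_2 - n_within_2],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate 2x2 table: a zero column marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ------------------------------------------------------ condition channels


def condition_channels(
    data: ConditionData,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> dict[str, np.ndarray]:
    """Per-second radiance channels of one condition.

    Returns ``w_det1`` (object ROI), ``w_det2`` (reference ROI) from the
    per-frame trimmed-mean apparent temperatures, and ``w_tmt_rs`` from
    the thermistor log resampled/aligned to frame timestamps.
    """
    t_obj = extract_roi_series(data.frames, "object", trim_fraction)
    t_ref = extract_roi_series(data.frames, "reference", trim_fraction)
    therm = data.thermistor
    if len(therm) == data.frames.n_frames:
        t_tmt = therm["temperature_C"].to_numpy()
    else:
        t_tmt = np.interp(
            data.frames.timestamps,
            therm["time_s"].to_numpy(),
            therm["temperature_C"].to_numpy(),
        )
    return {
        "w_det1": apparent_temperature_to_radiance_series(t_obj, constants),
        "w_det2": apparent_temperature_to_radiance_series(t_ref, constants),
        "w_tmt_rs": apparent_temperature_to_radiance_series(t_tmt, constants),
    }


def correct_condition(
    data: ConditionData,
    equation_id: str,
    calibration: CameraCalibration | None = None,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Per-second corrected object temperature (degC) for one equation.

    eq3 uses the known incubator set temperature for the ambient radiance;
    eq8 substitutes the in-scene reference; eq9/eq10 additionally apply
    the supplied per-camera calibration (they share one formula and differ
    only in how the coefficients were fitted).
    """
    if equation_id not in EQUATIONS:
        raise ValueError(f"unknown equation {equation_id!r}; expected one of {EQUATIONS}")
    ch = condition_channels(data, trim_fraction, constants)
    truth = data.truth
    inputs = CorrectionInputs(
        w_det1=ch["w_det1"],
        w_det2=ch["w_det2"],
        w_amb=celsius_to_radiance(truth["t_set_incu"], constants),
        w_tmt_rs=ch["w_tmt_rs"],
        eps_obj=truth["eps_obj"],
        eps_rs=truth["eps_rs"],
        tau_atm=truth["tau_atm"],
    )
    if equation_id == "eq3":
        return conventional_correction(inputs, constants).temperature_c
    if equation_id == "eq8":
        return reference_correction(inputs, constants).temperature_c
    if calibration is None:
        raise ValueError(f"{equation_id} requires a CameraCalibration")
    return linear_correction(inputs, calibration, constants).temperature_c


# ----------------------------------------------------------- calibration


def calibration_points(
    grid: list[GridCondition],
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-condition calibration tuples (predictor, w_tmt_rs, w_true).

    The predictor is the per-condition average of the difference channel
    (W_det1 - W_det2)/(eps_obj * tau); the true radiance comes from the
    object's set temperature.
    """
    xs, w_tmts, w_trues = [], [], []
    for cond in grid:
        ch = condition_channels(cond.data, trim_fraction, constants)
        truth = cond.data.truth
        x = (ch["w_det1"] - ch["w_det2"]) / (truth["eps_obj"] * truth["tau_atm"])
        xs.append(aggregate_condition(x))
        w_tmts.append(aggregate_condition(ch["w_tmt_rs"]))
        w_trues.append(truth["w_obj_true"])
    return np.array(xs), np.array(w_tmts), np.array(w_trues)


def fit_grid_calibration(
    grid: list[GridCondition],
    camera_id: str = "camera",
    two_point: bool = False,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> CameraCalibration:
    """Fit the linear-correction coefficients from a simulated/measured grid.

    With ``two_point=True`` only the two conditions with the largest
    object-incubator temperature differences of either sign are used,
    mirroring the reduced two-condition calibration protocol.
    """
    if two_point:
        conds = [(c.config.t_set_obj, c.config.t_set_incu, c.config.rh_set_incu) for c in grid]
        chosen = two_point_subset(conds)
        grid = [c for c, cond in zip(grid, conds) if cond in chosen]
        # keep one grid entry per chosen condition
        seen, subset = set(), []
        for c in grid:
            key = (c.config.t_set_obj, c.config.t_set_incu, c.config.rh_set_incu)
            if key not in seen:
                seen.add(key)
                subset.append(c)
        grid = subset
    x, w_tmt, w_true = calibration_points(grid, trim_fraction, constants)
    return fit_linear_coefficients(x, w_tmt, w_true, camera_id=camera_id)


# -------------------------------------------------------------- pipeline


def _evaluate_one(
    cond: GridCondition,
    equation_id: str,
    calibration: CameraCalibration | None,
    trim_fraction: float,
    constants: RadiometricConstants,
) -> ConditionResult:
    est = correct_condition(cond.data, equation_id, calibration, trim_fraction, constants)
    truth_t = cond.data.truth["t_set_obj"]
    abs_err = np.abs(est - truth_t)
    mae_c = float(abs_err.mean())
    sd_err = float(abs_err.std(ddof=1)) if abs_err.size > 1 else 0.0
    sd_est = float(np.std(est, ddof=1)) if est.size > 1 else 0.0
    mean_est = float(np.mean(est))
    return ConditionResult(
        condition_label=cond.label,
        equation_id=equation_id,
        mae=mae_c,
        sd=sd_err,
        sd_estimates=sd_est,
        mean_estimate=mean_est,
        within_tolerance=bool(mae_c <= ACCURACY_GATE_C),
        stable=bool(sd_err < STABILITY_GATE_C),
        within_point=bool(abs(mean_est - truth_t) <= ACCURACY_GATE_C),
    )


def evaluate_pipeline(
    grid: list[GridCondition],
    calibrations: dict[str, CameraCalibration] | None = None,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """Run every correction equation over a condition grid.

    Parameters
    ----------
    grid : list of GridCondition
        Simulated (or loaded) conditions.
    calibrations : dict, optional
        Maps "eq9" and/or "eq10" to their fitted CameraCalibration.  The
        regression equations are skipped with a warning when absent.

    Returns
    -------
    (results, summary)
        ``results`` — one row per condition x equation with MAE, error SD,
        estimate SD, flags.  ``summary`` — per-equation accuracy
        percentages and counts, plus all pairwise chi-square comparisons
        (``None`` where a table is degenerate, e.g. two equations both at
        100%).
    """
    if not grid:
        raise ValueError("empty condition grid")
    calibrations = calibrations or {}
    equations = ["eq3", "eq8"]
    for eq in ("eq9", "eq10"):
        if eq in calibrations:
            equations.append(eq)
        else:
            warnings.warn(f"no calibration supplied for {eq}; skipping", stacklevel=2)

    rows = [
        _evaluate_one(cond, eq, calibrations.get(eq), trim_fraction, constants)
        for cond in grid
        for eq in equations
    ]
    results = pd.DataFrame([asdict(r) for r in rows])

    summary: dict = {"n_conditions": len(grid), "equations": {}, "comparisons": {}}
    for eq in equations:
        sub = results[results.equation_id == eq]
        n_within = int(sub.within_tolerance.sum())
        summary["equations"][eq] = {
            "n_within": n_within,
            "n_total": int(len(sub)),
            "accuracy_pct": accuracy_percentage(sub.within_tolerance.to_numpy()),
            "accuracy_pct_point": accuracy_percentage(sub.within_point.to_numpy()),
            "stable_pct": accuracy_percentage(sub.stable.to_numpy()),
            "mean_mae": float(sub.mae.mean()),
        }
    for i, eq_a in enumerate(equations):
        for eq_b in equations[i + 1 :]:
            ga, gb = summary["equations"][eq_a], summary["equations"][eq_b]
            try:
                chi2, p = chi_square_accuracy(
                    ga["n_within"], ga["n_total"], gb["n_within"], gb["n_total"]
                )
                summary["comparisons"][f"{eq_a}_vs_{eq_b}"] = {
                    "chi2": chi2,
                    "p_value": p,
                }
            except ValueError:
                summary["comparisons"][f"{eq_a}_vs_{eq_b}"] = None
    return results, summary
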