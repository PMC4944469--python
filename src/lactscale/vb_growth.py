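"""Generalized Von Bertalanffy decomposition of cumulative intake elevation.

The cumulative elevation of maternal energy intake above the initial rate
is modelled, per pattern, by the generalized Von Bertalanffy growth curve

    C(t) = A * (1 - exp(-k t))^c

with ``A`` the asymptote (MJ), ``k`` a rate constant (1/day) and ``c`` a
dimensionless exponent controlling curvature. Its derivative, the extra
intake above the initial rate,

    C'(t) = A c k exp(-k t) (1 - exp(-k t))^(c-1)

has, for ``c > 1``, an interior maximum at ``t* = ln(c)/k``. Evaluating
the curve and its derivative at ``t*`` gives model-based versions of three
pattern characteristics:

    time to peak        t*   = ln(c) / k
    amplitude           C'(t*) = A k (1 - 1/c)^(c-1)
    cumulative to peak  C(t*)  = A (1 - 1/c)^c

These are linked by the exact identity

    C(t*) = amplitude * t* * shape,   shape = (1 - 1/c) / ln(c),

where *shape* (natural logarithm; the identity fails for any other base)
summarises the curvature of the elevation: 0.5 for a perfectly linear
rise (a right-triangle area), > 0.5 for a concave-down (decelerating)
rise, < 0.5 for a concave-up (accelerating) one. ``shape`` decreases
strictly from 1 (as c -> 1+) to 0 (as c -> infinity).

Fitting is ordinary nonlinear least squares on the cumulative series;
goodness of fit is the RMSE normalized by the observed range, reported
for both the cumulative and the rate series. Abnormal fits are screened
by Tukey fences on the relative difference between the model and raw
time to peak across the cohort of fitted patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "VBFit",
    "NoInteriorPeakError",
    "FitError",
    "vb_cumulative",
    "vb_rate",
    "shape_parameter",
    "derived_characteristics",
    "fit_vb",
    "normalized_rmse",
    "detect_abnormal_fits",
]

# Box constraints for the optimizer: c <= 1 has no interior peak, so the
# decomposition would be undefined; the upper bounds keep the search in the
# regime where the curve is a sigmoid on the observed time scale.
_K_MAX = 10.0
_C_MIN = 1.0 + 1e-6
_C_MAX = 100.0
_A_MAX_FACTOR = 10.0


class NoInteriorPeakError(ValueError):
    """The rate has no interior maximum (requires c > 1)."""


class FitError(RuntimeError):
    """The series cannot be fitted (degenerate input)."""


def _check_params(A: float, k: float, c: float) -> None:
    if A <= 0 or k <= 0 or c <= 0:
        raise ValueError(f"require A > 0, k > 0, c > 0; got A={A}, k={k}, c={c}")


def vb_cumulative(A: float, k: float, c: float, t):
    """Cumulative elevation ``A * (1 - exp(-k t))^c`` at time(s) ``t`` (MJ)."""
    _check_params(A, k, c)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = A * np.power(-np.expm1(-k * t), c)
    return out if out.ndim else float(out)


def vb_rate(A: float, k: float, c: float, t):
    """Extra intake above the initial rate, ``dC/dt`` (MJ/day)."""
    _check_params(A, k, c)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    g = -np.expm1(-k * t)  # 1 - exp(-kt), in [0, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = A * c * k * np.exp(-k * t) * np.power(g, c - 1.0)
    # at t = 0: limit is 0 for c > 1, A*k for c = 1, +inf for c < 1
    at0 = ~(g > 0)
    if np.any(at0):
        lim = 0.0 if c > 1 else (A * k if c == 1 else np.inf)
        out = np.where(at0, lim, out)
    return out if out.ndim else float(out)


def shape_parameter(c: float) -> float:
    """Curvature summary ``(1 - 1/c) / ln(c)`` of the elevation pattern."""
    if c <= 1:
        raise NoInteriorPeakError(f"shape is defined for c > 1; got c={c}")
    return (1.0 - 1.0 / c) / np.log(c)


def derived_characteristics(A: float, k: float, c: float) -> dict[str, float]:
    """Model-based pattern characteristics from fitted (A, k, c).

    Requires ``c > 1`` (interior peak). Returns a dict with keys
    ``time_to_peak`` (days), ``amplitude`` (MJ/day), ``cumulative_to_peak``
    (MJ) and ``shape`` (dimensionless).
    """
    _check_params(A, k, c)
    if c <= 1:
        raise NoInteriorPeakError(
            f"c must exceed 1 for the rate to have an interior peak; got c={c}"
        )
    one_m = 1.0 - 1.0 / c
    return {
        "time_to_peak": np.log(c) / k,
        "amplitude": A * k * one_m ** (c - 1.0),
        "cumulative_to_peak": A * one_m**c,
        "shape": one_m / np.log(c),
    }


@dataclass
class VBFit:
    """Result of fitting the growth curve to one cumulative-elevation series."""

    pattern_id: str
    A: float
    k: float
    c: float
    converged: bool
    nrmse_cumulative: float
    nrmse_rate: float | None = None
    derived: dict[str, float] = field(default_factory=dict)
    abnormal: bool = False
    abnormal_reason: str = ""
    message: str = ""


def normalized_rmse(observed, fitted) -> float:
    """RMSE divided by the range (max - min) of the observations.

    Returns NaN (with a warning) when the observed range is zero, where
    the normalization is undefined.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.size < 2 or observed.shape != fitted.shape:
        raise ValueError("need >= 2 paired observations")
    rng = float(np.max(observed) - np.min(observed))
    rmse = float(np.sqrt(np.mean((observed - fitted) ** 2)))
    if rng == 0.0:
        warnings.warn("observed range is zero; normalized RMSE undefined")
        return float("nan")
    return rmse / rng


def _vb_residuals(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    A, k, c = params
    return A * np.power(-np.expm1(-k * t), c) - y


def fit_vb(
    t,
    cumulative,
    pattern_id: str = "",
    t_peak_guess: float | None = None,
) -> VBFit:
    """Least-squares fit of the growth curve to one cumulative series.

    Parameters
    ----------
    t, cumulative : array-like
        Time since the initial-rate measurement (days, ``t[0] == 0``) and
        the cumulative elevation there (MJ, ``cumulative[0] == 0``).
    t_peak_guess : float, optional
        Starting guess for the time to peak; defaults to the time of the
        largest observed increment. Initialization follows the sigmoid
        geometry: ``A0 = 1.05 x max(C)``, ``c0 = 2``,
        ``k0 = ln(c0) / t_peak_guess``.

    Raises
    ------
    FitError
        If the series is degenerate (all zeros, or too short).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(cumulative, dtype=float)
    if t.size < 3 or t.shape != y.shape:
        raise FitError(f"{pattern_id}: need >= 3 paired (t, cumulative) points")
    if np.all(y == 0.0) or np.max(np.abs(y)) == 0.0:
        raise FitError(f"{pattern_id}: constant-zero elevation series")

    ymax = float(np.max(y))
    if ymax <= 0:
        raise FitError(f"{pattern_id}: cumulative elevation never positive")
    if t_peak_guess is None or t_peak_guess <= 0:
        inc = np.diff(y)
        t_peak_guess = float(t[1 + int(np.argmax(inc))]) if inc.size else float(t[-1])
        t_peak_guess = max(t_peak_guess, float(t[t.size // 2]), 1e-6)

    lower = np.array([1e-8, 1e-6, _C_MIN])
    upper = np.array([_A_MAX_FACTOR * ymax, _K_MAX, _C_MAX])

    best = None
    for c0 in (2.0, 1.5, 5.0):
        k0 = np.log(c0) / t_peak_guess
        x0 = np.clip(np.array([1.05 * ymax, k0, c0]), lower, upper)
        try:
            res = least_squares(
                _vb_residuals, x0, args=(t, y), bounds=(lower, upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:  # numerical failure for this start
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
        if best is not None and c0 == 2.0:
            break  # default start succeeded; keep it

    if best is None:
        return VBFit(pattern_id, np.nan, np.nan, np.nan, converged=False,
                     nrmse_cumulative=np.nan, message="optimizer did not converge")

    A, k, c = (float(v) for v in best.x)
    fitted = vb_cumulative(A, k, c, t)
    nrmse = normalized_rmse(y, fitted)
    try:
        derived = derived_characteristics(A, k, c)
    except NoInteriorPeakError:
        derived = {}
    return VBFit(pattern_id, A, k, c, converged=True, nrmse_cumulative=nrmse,
                 derived=derived, message=best.message)


def detect_abnormal_fits(
    model_t_peak,
    raw_t_peak,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag fits whose model time-to-peak deviates abnormally from the raw one.

    Computes, per fit, the relative difference
    ``r = (t_peak_model - t_peak_raw) / t_peak_raw`` and flags fits whose
    ``r`` lies outside the Tukey fences ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` of
    the cohort's ``r`` distribution. With a cohort of fewer than 4 fits the
    screening is skipped (nothing flagged) with a warning; a zero-IQR
    cohort flags nothing.

    Returns ``(flags, r)`` as aligned arrays.
    """
    model_t_peak = np.asarray(model_t_peak, dtype=float)
    raw_t_peak = np.asarray(raw_t_peak, dtype=float)
    if model_t_peak.shape != raw_t_peak.shape:
        raise ValueError("model and raw time-to-peak arrays must align")
    r = (model_t_peak - raw_t_peak) / raw_t_peak
    ok = np.isfinite(r)
    if np.sum(ok) < 4:
        warnings.warn("fewer than 4 comparable fits; abnormal-fit screening skipped")
        return np.zeros(r.shape, dtype=bool), r
    q1, q3 = np.percentile(r[ok], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = ok & ((r < lo) | (r > hi))
    return flags, r
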