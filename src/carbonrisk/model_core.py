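"""Logistic transfer mathematics for annual disaster incidence.

The transfer maps a linear predictor -- lagged CO2 concentration growth,
log-covariates, a persistence term and fixed effects -- to a probability.
Everything downstream (calibration, certainty equivalents, the uncertainty
wedge, response coefficients and count projections) is built on top of it.

Unit conventions
----------------
CO2 growth rates (``mu_c``, ``sigma_c``, the series ``c_t``) are carried in
percent per annum everywhere *except* :func:`cumulative_response`, which takes
the mean growth as a fraction (e.g. ``0.01624``).  Both conventions are made
explicit per call; mixing them up moves results by two orders of magnitude,
hence the plausibility warning in :func:`certainty_equivalent`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "LogitParams",
    "TransferPoint",
    "ResponseReport",
    "UnitMismatchWarning",
    "CalibrationError",
    "logistic_transfer",
    "tanh_identity_residual",
    "linear_index",
    "certainty_equivalent",
    "calibrate_intercept",
    "calibrated_params",
    "uncertainty_wedge",
    "cumulative_response",
    "project_disaster_growth",
    "doubling_time",
    "response_report",
    "round_half_away",
]

#: Plausibility band for mean CO2 growth in percent p.a.  Values outside it
#: usually mean the caller passed a fraction where percent was expected.
PLAUSIBLE_MU_C_PCT = (-5.0, 10.0)


class UnitMismatchWarning(UserWarning):
    """Mean CO2 growth lies outside the configured plausibility band."""


class CalibrationError(ValueError):
    """Raised when calibration inputs are outside their admissible domain."""


def _as_finite_float(x, name: str) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x


@dataclass(frozen=True)
class LogitParams:
    """Coefficients of the logistic incidence transfer.

    Parameters
    ----------
    intercept :
        Log-odds scaling constant (``h_bar``).
    lag_coeffs :
        Elasticities per lag of CO2 growth, ``h_0 .. h_P`` (growth in
        percent p.a.).  ``P = len(lag_coeffs) - 1``.
    control_coeffs :
        Elasticities per log-covariate (``gamma_k``).
    persistence :
        Coefficient on the lagged dependent term (``delta``).
    country_effects, time_effects :
        Log-odds offsets per country / calendar year.  Keys not present
        default to 0.
    calibration_target :
        Incidence the intercept was calibrated to, or ``None`` if the
        intercept has not been calibrated (see :func:`calibrated_params`).
    """

    intercept: float
    lag_coeffs: tuple[float, ...]
    control_coeffs: tuple[float, ...] = ()
    persistence: float = 0.0
    country_effects: Mapping[str, float] = field(default_factory=dict)
    time_effects: Mapping[int, float] = field(default_factory=dict)
    calibration_target: float | None = None

    def __post_init__(self):
        if len(self.lag_coeffs) < 1:
            raise ValueError("at least one lag coefficient (h_0) is required")
        object.__setattr__(self, "lag_coeffs", tuple(float(h) for h in self.lag_coeffs))
        object.__setattr__(self, "control_coeffs", tuple(float(g) for g in self.control_coeffs))

    @property
    def lag_order(self) -> int:
        """Lag order ``P`` (number of lag coefficients minus one)."""
        return len(self.lag_coeffs) - 1

    @property
    def lag_sum(self) -> float:
        """Cumulative carbon elasticity ``sum_j h_j``."""
        return float(sum(self.lag_coeffs))

    def country_effect(self, country) -> float:
        return float(self.country_effects.get(country, 0.0))

    def time_effect(self, year) -> float:
        return float(self.time_effects.get(year, 0.0))

    @property
    def is_calibrated(self) -> bool:
        return self.calibration_target is not None


@dataclass(frozen=True)
class TransferPoint:
    """Evaluation point of the transfer: means of all model inputs.

    ``mu_c`` is mean CO2 growth in percent p.a.; ``covariate_means`` are the
    means of the transforms entering the model (e.g. log urban share);
    ``lagged_incidence`` is the probability entering the persistence term.
    Fixed-effect means default to 0.
    """

    mu_c: float
    covariate_means: tuple[float, ...] = ()
    lagged_incidence: float = 0.0
    country_effect_mean: float = 0.0
    time_effect_mean: float = 0.0

    def __post_init__(self):
        _as_finite_float(self.mu_c, "mu_c")
        if not 0.0 <= self.lagged_incidence <= 1.0:
            raise ValueError(f"lagged_incidence must be in [0, 1], got {self.lagged_incidence}")
        object.__setattr__(
            self, "covariate_means", tuple(float(m) for m in self.covariate_means)
        )


def logistic_transfer(x):
    """Logistic (sigmoid) map ``exp(x) / (1 + exp(x))``.

    Numerically stable for large ``|x|``; accepts scalars or arrays.
    Non-finite inputs raise ``ValueError``.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logistic_transfer requires finite input")
    out = expit(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def tanh_identity_residual(x) -> float:
    """Residual of the identity ``sigma(x) - 1/2 = tanh(x/2) / 2``.

    Zero to within 1e-12 for ``|x| <= 30``; useful as a self-check of the
    transfer implementation.
    """
    x = _as_finite_float(x, "x")
    return logistic_transfer(x) - 0.5 - 0.5 * math.tanh(x / 2.0)


def linear_index(params: LogitParams, point: TransferPoint) -> float:
    """Log-odds linear predictor of the transfer at a mean point.

    All lags are evaluated at the common mean ``mu_c`` (stationarity), so the
    carbon contribution collapses to ``lag_sum * mu_c``.
    """
    if len(params.control_coeffs) != len(point.covariate_means):
        raise ValueError(
            f"{len(params.control_coeffs)} control coefficients but "
            f"{len(point.covariate_means)} covariate means supplied"
        )
    return (
        params.intercept
        + params.lag_sum * point.mu_c
        + float(np.dot(params.control_coeffs, point.covariate_means))
        + params.persistence * point.lagged_incidence
        + point.country_effect_mean
        + point.time_effect_mean
    )


def certainty_equivalent(params: LogitParams, point: TransferPoint) -> float:
    """Certainty-equivalent incidence: the transfer evaluated at the means.

    Warns (without failing) when ``mu_c`` falls outside the percent-p.a.
    plausibility band, a common symptom of passing a fraction.
    """
    lo, hi = PLAUSIBLE_MU_C_PCT
    if not lo <= point.mu_c <= hi:
        warnings.warn(
            f"mu_c={point.mu_c} outside the plausibility band {PLAUSIBLE_MU_C_PCT} "
            "for percent p.a.; check units",
            UnitMismatchWarning,
            stacklevel=2,
        )
    return logistic_transfer(linear_index(params, point))


def calibrate_intercept(params: LogitParams, point: TransferPoint, target: float) -> float:
    """Intercept making the certainty equivalent at ``point`` equal ``target``.

    Closed form: ``logit(target)`` minus every non-intercept term of the
    linear predictor.  ``target`` must lie strictly inside (0, 1).
    """
    target = float(target)
    if not 0.0 < target < 1.0:
        raise CalibrationError(f"target incidence must be in (0, 1), got {target}")
    base = linear_index(replace(params, intercept=0.0), point)
    return float(_logit(target)) - base


def calibrated_params(params: LogitParams, point: TransferPoint, target: float) -> LogitParams:
    """Copy of ``params`` with the intercept calibrated to ``target`` at ``point``."""
    h_bar = calibrate_intercept(params, point, target)
    return replace(params, intercept=h_bar, calibration_target=float(target))


def uncertainty_wedge(expected_p: float, mu_p_bar: float) -> float:
    """Wedge ``E[p] - mu_p_bar`` between expected and certainty-equivalent incidence.

    May be negative if the expectation is taken past the inflection point of
    the transfer; no clamping is applied.
    """
    for name, v in (("expected_p", expected_p), ("mu_p_bar", mu_p_bar)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
    return float(expected_p) - float(mu_p_bar)


def cumulative_response(lag_sum: float, mu_c_fraction: float) -> float:
    """Cumulative response ``d ln(mu_p_bar) / d mu_c`` of incidence to CO2 growth.

    ``lag_sum * exp(-m S) / (1 + exp(-m S))`` with ``S`` the lag sum and ``m``
    mean CO2 growth supplied *as a fraction* (e.g. ``0.01624``).  Algebraically
    equal to ``S * (1 - logistic_transfer(S * m))``.
    """
    lag_sum = _as_finite_float(lag_sum, "lag_sum")
    m = _as_finite_float(mu_c_fraction, "mu_c_fraction")
    return lag_sum * float(expit(-m * lag_sum))


def project_disaster_growth(response: float, co2_rise_pct: float) -> float:
    """Percent-per-year growth in disaster counts from a CO2 stock rise.

    ``response`` is the cumulative response coefficient (dimensionless,
    must be >= 0); ``co2_rise_pct`` the percent rise in the CO2 stock.
    """
    response = _as_finite_float(response, "response")
    if response < 0:
        raise ValueError(f"response must be >= 0, got {response}")
    return response * _as_finite_float(co2_rise_pct, "co2_rise_pct")


def doubling_time(annual_growth: float) -> int:
    """Smallest integer ``n`` of years with ``(1 + g)^n >= 2``.

    ``annual_growth`` is a fraction per year (0.0488 for 4.88 % p.a.) and must
    be strictly positive.
    """
    g = _as_finite_float(annual_growth, "annual_growth")
    if g <= 0:
        raise CalibrationError(f"no doubling for annual_growth <= 0 (got {g})")
    n = math.ceil(math.log(2.0) / math.log1p(g))
    # guard against float rounding at the boundary
    while n > 1 and (1.0 + g) ** (n - 1) >= 2.0:
        n -= 1
    while (1.0 + g) ** n < 2.0:
        n += 1
    return int(n)


@dataclass(frozen=True)
class ResponseReport:
    """Response coefficient plus its disaster-count projection."""

    response: float
    annual_growth_pct: float
    doubling_years: int
    base_count: float
    doubled_count: float

    def __post_init__(self):
        if self.annual_growth_pct > 0 and self.doubling_years < 1:
            raise ValueError("doubling_years must be >= 1 for positive growth")
        if not math.isclose(self.doubled_count, 2.0 * self.base_count, rel_tol=1e-12):
            raise ValueError("doubled_count must equal 2 x base_count")


def response_report(
    lag_sum: float,
    mu_c_fraction: float,
    co2_rise_pct: float,
    base_count: float,
) -> ResponseReport:
    """Bundle response coefficient, implied growth and doubling time."""
    resp = cumulative_response(lag_sum, mu_c_fraction)
    growth_pct = project_disaster_growth(resp, co2_rise_pct)
    years = doubling_time(growth_pct / 100.0)
    return ResponseReport(
        response=resp,
        annual_growth_pct=growth_pct,
        doubling_years=years,
        base_count=float(base_count),
        doubled_count=2.0 * float(base_count),
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-table convention, not banker's)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
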