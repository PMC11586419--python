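"""Canonical published coefficient presets used as calibration inputs.

These are point estimates from the published 1960-2022 estimation record
(EM-DAT disaster panel, NOAA CO2 growth) and serve as default inputs for
calibration, simulation and scenario evaluation.  Intercepts are *not*
carried here: they are always derived via :func:`carbonrisk.model_core.calibrated_params`
against the historical incidence target.
"""

from __future__ import annotations

import math

from .model_core import LogitParams, TransferPoint, calibrated_params

__all__ = [
    "BASELINE_INCIDENCE",
    "INCIDENCE_SD",
    "BASELINE_MU_C",
    "BASELINE_SIGMA_C",
    "SIGMA_C_MIN",
    "AR3_RHO",
    "AR3_SIGMA_XI",
    "RCP_MU_C",
    "CO2_RISE_2015_2022_PCT",
    "MEAN_ANNUAL_DISASTERS",
    "LOGIT_ESTIMATES",
    "baseline_point",
    "baseline_calibrated",
]

#: Pooled annual disaster incidence over 1960-2022 (fraction).
BASELINE_INCIDENCE = 0.062
#: Cross-sectional standard deviation of annual incidence (fraction).
INCIDENCE_SD = 0.056
#: Mean annual CO2 concentration growth 1960-2022, percent p.a.
BASELINE_MU_C = 1.624
#: Stationary standard deviation of annual CO2 growth, percent p.a.
BASELINE_SIGMA_C = 0.68
#: Stabilised-concentration scenario standard deviation, percent p.a.
SIGMA_C_MIN = 0.30
#: AR(3) autoregressive coefficients for annual CO2 growth.
AR3_RHO = (0.2598, 0.2149, 0.3212)
#: AR(3) innovation standard deviation, percent p.a.
AR3_SIGMA_XI = 0.544
#: Mean CO2 growth 2023-2100 implied by each RCP 2100 stock level, percent p.a.
RCP_MU_C = {
    "RCP2.6": 0.19,
    "RCP3.4": 0.34,
    "RCP4.5": 0.56,
    "RCP6": 0.91,
    "RCP8.5": 1.54,
}
#: Cumulative percent rise in the CO2 stock over 2015-2022 (~17.5 ppm on ~401).
CO2_RISE_2015_2022_PCT = 4.4
#: 2002-2021 average disaster count per country-year.
MEAN_ANNUAL_DISASTERS = 1.71

# Published logit estimates keyed by (fixed-effect mode, control set).
# Intercepts left at 0.0 and must be calibrated before use.
LOGIT_ESTIMATES: dict[tuple[str, str], LogitParams] = {
    ("none", "none"): LogitParams(
        intercept=0.0,
        lag_coeffs=(0.497, 0.347, 0.423, 0.297),
        persistence=0.496,
    ),
    ("none", "urban"): LogitParams(
        intercept=0.0,
        lag_coeffs=(0.485, 0.305, 0.358, 0.272),
        control_coeffs=(0.747,),
        persistence=0.421,
    ),
    ("one_way", "none"): LogitParams(
        intercept=0.0,
        lag_coeffs=(0.504, 0.360, 0.432, 0.306),
        persistence=0.382,
    ),
    ("one_way", "urban"): LogitParams(
        intercept=0.0,
        lag_coeffs=(0.456, 0.277, 0.326, 0.245),
        control_coeffs=(1.276,),
        persistence=0.296,
    ),
    ("two_way", "none"): LogitParams(
        intercept=0.0,
        lag_coeffs=(-0.279, 0.616, 1.242, 0.603),
        persistence=0.175,
    ),
    ("two_way", "urban"): LogitParams(
        intercept=0.0,
        lag_coeffs=(-1.693, 1.200, 1.719, 1.033),
        control_coeffs=(0.204,),
        persistence=0.121,
    ),
}

#: Mean log urban population share used at the baseline evaluation point.
#: Its value is absorbed by the calibrated intercept, so it only anchors the
#: point at which non-carbon terms are held fixed.
MEAN_LOG_URBAN_SHARE = math.log(0.5)


def baseline_point(params: LogitParams, mu_c: float = BASELINE_MU_C) -> TransferPoint:
    """Historical-baseline evaluation point matching ``params``' covariates."""
    return TransferPoint(
        mu_c=mu_c,
        covariate_means=(MEAN_LOG_URBAN_SHARE,) * len(params.control_coeffs),
        lagged_incidence=BASELINE_INCIDENCE,
    )


def baseline_calibrated(
    fe: str = "one_way", control: str = "urban", target: float = BASELINE_INCIDENCE
) -> tuple[LogitParams, TransferPoint]:
    """Published estimates with the intercept calibrated at the baseline point."""
    params = LOGIT_ESTIMATES[(fe, control)]
    point = baseline_point(params)
    return calibrated_params(params, point, target), point
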