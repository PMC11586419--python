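"""Monte-Carlo decomposition of disaster risk into certainty equivalent and wedge.

Carbon growth paths from the AR process are pushed through the logistic
transfer; per-run incidence statistics and cross-run percentile confidence
intervals quantify expected risk, its dispersion, and the Jensen-inequality
uncertainty wedge relative to the certainty equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .carbon_dynamics import ARFit, ShockSpec, simulate_growth_paths
from .model_core import (
    LogitParams,
    TransferPoint,
    calibrated_params,
    certainty_equivalent,
    logistic_transfer,
)

__all__ = [
    "Band",
    "SimulationConfig",
    "SimulationSummary",
    "SimulationResult",
    "BetaBenchmark",
    "simulate_incidence",
    "expected_wedge",
    "fit_beta_benchmark",
    "fit_beta_ml",
    "rmse_vs_beta",
    "convexity_percentile_run",
]


@dataclass(frozen=True)
class Band:
    """Point value with a 95% cross-run percentile interval."""

    point: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"CI lower {self.lower} exceeds upper {self.upper}")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of an incidence simulation.

    ``dynamic`` selects the persistence recursion: ``"probability"``
    (deterministic recursion on the previous simulated probability,
    initialised at the certainty equivalent) or ``"bernoulli"`` (persistence
    multiplies a drawn lagged state).
    """

    params: LogitParams
    point: TransferPoint
    carbon: ARFit
    runs: int = 2000
    horizon: int = 2000
    burn_in: int = 500
    shocks: ShockSpec = field(default_factory=ShockSpec)
    dynamic: str = "probability"
    seed: int | None = None

    def __post_init__(self):
        if self.runs < 1 or self.horizon < 1:
            raise ValueError("runs and horizon must be >= 1")
        if self.dynamic not in ("probability", "bernoulli"):
            raise ValueError(f"unknown dynamic mode {self.dynamic!r}")


@dataclass(frozen=True)
class SimulationSummary:
    """Cross-run incidence statistics with 95% percentile bands (fractions)."""

    mean: Band
    sd: Band
    skewness: Band
    kurtosis: Band
    certainty_equivalent: float
    expected_wedge: Band
    rmse_vs_beta: float | None = None
    runs: int = 0
    horizon: int = 0


@dataclass
class SimulationResult:
    """Summary plus (optionally) the simulated incidence trajectories."""

    summary: SimulationSummary
    trajectories: np.ndarray | None = None
    per_run_means: np.ndarray | None = None


def _band(values: np.ndarray) -> Band:
    return Band(
        point=float(np.mean(values)),
        lower=float(np.percentile(values, 2.5)),
        upper=float(np.percentile(values, 97.5)),
    )


def simulate_incidence(
    config: SimulationConfig,
    return_trajectories: bool = False,
    carbon_paths: np.ndarray | None = None,
    allow_uncalibrated: bool = False,
) -> SimulationResult:
    """Simulate stochastic incidence paths and summarise them.

    For each run the carbon path is simulated (or taken from ``carbon_paths``,
    shaped ``(runs, horizon + lag_order)``), the log-odds assembled as
    ``h_bar + sum_j h_j c_{t-j} + gamma . mu_k + delta * (lagged term)`` with
    covariates held at their point means, and the logistic transfer applied.
    Refuses parameters without a calibrated intercept unless
    ``allow_uncalibrated=True``.
    """
    params, point = config.params, config.point
    if not params.is_calibrated and not allow_uncalibrated:
        raise ValueError(
            "params have no calibrated intercept; calibrate first or pass allow_uncalibrated=True"
        )
    P = params.lag_order
    T = config.horizon
    rng = np.random.default_rng(config.seed)

    if carbon_paths is None:
        carbon_paths = simulate_growth_paths(
            config.carbon,
            config.runs,
            T + P,
            burn_in=config.burn_in,
            shocks=config.shocks,
            rng=rng,
        )
    else:
        carbon_paths = np.asarray(carbon_paths, dtype=float)
        if carbon_paths.shape != (config.runs, T + P):
            raise ValueError(f"carbon_paths must be shaped ({config.runs}, {T + P})")

    h = np.asarray(params.lag_coeffs)
    # carbon contribution for outcome t uses lags c[t+P], c[t+P-1], ..., c[t]
    carbon_term = np.zeros((config.runs, T))
    for j in range(P + 1):
        carbon_term += h[j] * carbon_paths[:, P - j : P - j + T]

    base = (
        params.intercept
        + float(np.dot(params.control_coeffs, point.covariate_means))
        + point.country_effect_mean
        + point.time_effect_mean
        + carbon_term
    )

    mu_p_bar = certainty_equivalent(params, point)
    delta = params.persistence
    p = np.empty((config.runs, T))
    if delta == 0.0:
        p[:] = logistic_transfer(base)
    else:
        prev = np.full(config.runs, mu_p_bar)
        for t in range(T):
            if config.dynamic == "bernoulli":
                lagged = rng.binomial(1, prev).astype(float) if t > 0 else prev
            else:
                lagged = prev
            prev = logistic_transfer(base[:, t] + delta * lagged)
            p[:, t] = prev

    run_mean = p.mean(axis=1)
    run_sd = p.std(axis=1, ddof=1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant trajectories
        run_skew = stats.skew(p, axis=1)
        run_kurt = stats.kurtosis(p, axis=1, fisher=False)

    mean_band = _band(run_mean)
    wedge_band = Band(
        point=mean_band.point - mu_p_bar,
        lower=mean_band.lower - mu_p_bar,
        upper=mean_band.upper - mu_p_bar,
    )
    summary = SimulationSummary(
        mean=mean_band,
        sd=_band(run_sd),
        skewness=_band(np.nan_to_num(run_skew)),
        kurtosis=_band(np.nan_to_num(run_kurt, nan=0.0)),
        certainty_equivalent=mu_p_bar,
        expected_wedge=wedge_band,
        runs=config.runs,
        horizon=T,
    )
    return SimulationResult(
        summary=summary,
        trajectories=p if return_trajectories else None,
        per_run_means=run_mean,
    )


def expected_wedge(summary: SimulationSummary) -> Band:
    """Expected uncertainty wedge ``E[mean incidence] - certainty equivalent``.

    The band is the cross-run mean interval shifted by the certainty
    equivalent (identity by construction).
    """
    return summary.expected_wedge


@dataclass(frozen=True)
class BetaBenchmark:
    """Beta distribution benchmark for incidence trajectories."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be > 0")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def fit_beta_benchmark(mean: float, sd: float) -> BetaBenchmark:
    """Moment-matched beta benchmark: closed-form alpha/beta from mean and sd."""
    m, v = float(mean), float(sd) ** 2
    if not 0.0 < m < 1.0:
        raise ValueError("mean must be in (0, 1)")
    if v <= 0 or v >= m * (1.0 - m):
        raise ValueError(f"variance {v} not attainable by a beta with mean {m}")
    nu = m * (1.0 - m) / v - 1.0
    return BetaBenchmark(alpha=m * nu, beta=(1.0 - m) * nu)


def fit_beta_ml(data) -> BetaBenchmark:
    """Maximum-likelihood beta fit on raw incidence data in (0, 1)."""
    x = np.asarray(data, dtype=float)
    x = np.clip(x, 1e-9, 1.0 - 1e-9)
    a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    return BetaBenchmark(alpha=float(a), beta=float(b))


def rmse_vs_beta(
    trajectories: np.ndarray, benchmark: BetaBenchmark, seed: int | None = None
) -> float:
    """Quantile-matched RMSE between trajectories and the beta benchmark.

    For each run an equal-length iid beta sample is drawn, both samples
    sorted, and the root-mean-square difference of order statistics taken;
    the cross-run mean is reported.
    """
    p = np.asarray(trajectories, dtype=float)
    if p.ndim != 2:
        raise ValueError("trajectories must be a (runs, horizon) array")
    rng = np.random.default_rng(seed)
    ref = rng.beta(benchmark.alpha, benchmark.beta, size=p.shape)
    diff = np.sort(p, axis=1) - np.sort(ref, axis=1)
    return float(np.mean(np.sqrt(np.mean(diff**2, axis=1))))


def convexity_percentile_run(
    fit,
    percentile: float,
    config: SimulationConfig,
    target: float | None = None,
    return_trajectories: bool = False,
) -> SimulationResult:
    """Re-run the simulation at a CI endpoint of the lag coefficients.

    ``fit`` is a :class:`carbonrisk.panel_estimation.LogitFit` (coefficient
    covariance required).  Each lag coefficient is replaced by its 2.5th or
    97.5th normal-approximation endpoint, the intercept recalibrated to the
    incidence target at ``config.point``, and the simulation re-run.
    """
    if percentile not in (2.5, 97.5):
        raise ValueError("percentile must be 2.5 or 97.5")
    z = stats.norm.ppf(percentile / 100.0)
    params = fit.params
    lag_cols = [f"c_lag{j}" for j in range(params.lag_order + 1)]
    ses = [float(fit.standard_errors[c]) for c in lag_cols]
    shifted = tuple(h + z * s for h, s in zip(params.lag_coeffs, ses))
    if target is None:
        target = config.params.calibration_target
        if target is None:
            raise ValueError("no incidence target available for recalibration")
    shifted_params = calibrated_params(
        replace(config.params, lag_coeffs=shifted), config.point, target
    )
    new_config = replace(config, params=shifted_params)
    return simulate_incidence(new_config, return_trajectories=return_trajectories)


def summary_table(summaries: Mapping[str, SimulationSummary], percent: bool = True):
    """Tidy (statistic, lower, upper) table for one or more summaries."""
    import pandas as pd

    scale = 100.0 if percent else 1.0
    records = []
    for label, s in summaries.items():
        for stat_name, band, scaled in (
            ("mean", s.mean, True),
            ("wedge", s.expected_wedge, True),
            ("sd", s.sd, True),
            ("skewness", s.skewness, False),
            ("kurtosis", s.kurtosis, False),
        ):
            f = scale if scaled else 1.0
            records.append(
                {
                    "run": label,
                    "statistic": stat_name,
                    "point": band.point * f,
                    "lower": band.lower * f,
                    "upper": band.upper * f,
                }
            )
        records.append(
            {
                "run": label,
                "statistic": "certainty_equivalent",
                "point": s.certainty_equivalent * scale,
                "lower": s.certainty_equivalent * scale,
                "upper": s.certainty_equivalent * scale,
            }
        )
    return pd.DataFrame.from_records(records)
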