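"""Stationary AR(p) modelling of annual CO2 concentration growth.

Estimation is conditional maximum likelihood (least squares on the lagged
design), stationary moments come from the closed-form Yule-Walker solution,
and simulation runs the AR recursion as an IIR filter so long paths and many
runs stay cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

__all__ = [
    "CarbonSeries",
    "ARFit",
    "ShockSpec",
    "NonstationaryError",
    "fit_ar",
    "select_order",
    "stationary_moments",
    "yule_walker_autocorrelations",
    "calibrate_intercept_ar",
    "rescale_innovation_sd",
    "simulate_carbon",
    "simulate_growth_paths",
    "bootstrap_moments",
    "ar_fit_from_coeffs",
]


class NonstationaryError(ValueError):
    """The AR coefficients do not define a stationary process."""


@dataclass(frozen=True)
class CarbonSeries:
    """Annual CO2 concentration levels (ppm) and percent growth rates.

    ``growth`` is in percent p.a.; when built from levels it is defined as
    ``100 * diff(log(levels))`` and is one observation shorter than the level
    track, with ``years`` aligned to the growth observations.
    """

    years: np.ndarray
    growth: np.ndarray
    levels: np.ndarray | None = None

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        growth = np.asarray(self.growth, dtype=float)
        if years.shape != growth.shape:
            raise ValueError("years and growth must have equal length")
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be strictly increasing with annual spacing")
        if not np.all(np.isfinite(growth)):
            raise ValueError("growth contains non-finite values")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "growth", growth)
        if self.levels is not None:
            levels = np.asarray(self.levels, dtype=float)
            if levels.shape != years.shape:
                raise ValueError("levels must align with years")
            object.__setattr__(self, "levels", levels)

    @classmethod
    def from_levels(cls, years, levels) -> "CarbonSeries":
        """Build a growth series from an annual ppm level track."""
        years = np.asarray(years, dtype=int)
        levels = np.asarray(levels, dtype=float)
        if np.any(levels <= 0):
            raise ValueError("levels must be positive")
        growth = 100.0 * np.diff(np.log(levels))
        return cls(years=years[1:], growth=growth, levels=levels[1:])

    def __len__(self) -> int:
        return len(self.growth)


@dataclass(frozen=True)
class ARFit:
    """AR(p) coefficients with innovation scale and fit diagnostics.

    ``diagnostics`` holds aic, sbic, durbin_watson, jarque_bera_p, adj_r2 and
    nobs when produced by :func:`fit_ar`; fits built directly from published
    coefficients carry an empty dict.
    """

    order: int
    intercept: float
    coeffs: tuple[float, ...]
    innovation_sd: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        coeffs = tuple(float(c) for c in self.coeffs)
        if len(coeffs) != self.order:
            raise ValueError(f"expected {self.order} coefficients, got {len(coeffs)}")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be >= 0")
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def is_stationary(self) -> bool:
        """Stationarity via companion-matrix eigenvalues inside the unit circle."""
        if self.order == 0:
            return True
        companion = np.zeros((self.order, self.order))
        companion[0, :] = self.coeffs
        if self.order > 1:
            companion[1:, :-1] = np.eye(self.order - 1)
        return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)

    @property
    def implied_mean(self) -> float:
        return stationary_moments(self)[0]

    @property
    def implied_sd(self) -> float:
        return stationary_moments(self)[1]


@dataclass(frozen=True)
class ShockSpec:
    """Innovation family for AR simulation.

    Gaussian shocks have standard deviation ``sigma_xi``.  Logistic shocks use
    location 0 and *scale* ``sigma_xi`` (so their standard deviation is
    ``sigma_xi * pi / sqrt(3)``); the parameterization is deliberate and
    recorded here.
    """

    family: str = "gaussian"
    seed: int | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "logistic"):
            raise ValueError(f"unknown shock family {self.family!r}")

    def draw(self, rng: np.random.Generator, sigma_xi: float, size) -> np.ndarray:
        if sigma_xi == 0.0:
            return np.zeros(size)
        if self.family == "gaussian":
            return rng.normal(0.0, sigma_xi, size=size)
        return rng.logistic(0.0, sigma_xi, size=size)


def ar_fit_from_coeffs(
    coeffs, sigma_xi: float, mean: float | None = None, intercept: float | None = None
) -> ARFit:
    """Convenience constructor from coefficients plus either a mean or intercept."""
    coeffs = tuple(float(c) for c in coeffs)
    if intercept is None:
        if mean is None:
            raise ValueError("supply either mean or intercept")
        intercept = (1.0 - sum(coeffs)) * float(mean)
    return ARFit(order=len(coeffs), intercept=float(intercept), coeffs=coeffs, innovation_sd=float(sigma_xi))


def fit_ar(series: CarbonSeries, order: int) -> ARFit:
    """Conditional-ML (least-squares) AR(p) fit with diagnostics.

    Requires more than ``order + 10`` observations.  A nonstationary estimate
    is flagged in ``diagnostics['stationary']`` rather than raised.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    c = series.growth
    n_total = len(c)
    if n_total <= order + 10:
        raise ValueError(f"series too short ({n_total}) for AR({order}) estimation")
    y = c[order:]
    n = len(y)
    X = np.column_stack([np.ones(n)] + [c[order - j : n_total - j] for j in range(1, order + 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    k = order + 1
    ssr = float(resid @ resid)
    sigma_xi = math.sqrt(ssr / (n - k)) if n > k else 0.0

    # Gaussian log-likelihood, per-observation AIC/SBIC convention
    sigma2_ml = ssr / n
    loglik = -0.5 * n * (1.0 + math.log(2.0 * math.pi) + math.log(max(sigma2_ml, 1e-300)))
    aic = (-2.0 * loglik + 2.0 * k) / n
    sbic = (-2.0 * loglik + k * math.log(n)) / n
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else r2
    dw = float(np.sum(np.diff(resid) ** 2) / ssr) if ssr > 0 else 0.0
    jb_p = float(stats.jarque_bera(resid).pvalue) if n >= 3 else float("nan")

    fit = ARFit(
        order=order,
        intercept=float(beta[0]),
        coeffs=tuple(beta[1:]),
        innovation_sd=sigma_xi,
        diagnostics={
            "aic": aic,
            "sbic": sbic,
            "durbin_watson": dw,
            "jarque_bera_p": jb_p,
            "adj_r2": adj_r2,
            "nobs": n,
            "loglik": loglik,
        },
    )
    fit.diagnostics["stationary"] = fit.is_stationary
    if not fit.is_stationary:
        import warnings

        warnings.warn("estimated AR coefficients are nonstationary", UserWarning, stacklevel=2)
    return fit


def select_order(series: CarbonSeries, orders=(1, 2, 3)) -> int:
    """Order with minimum AIC over the candidate set."""
    fits = {p: fit_ar(series, p) for p in orders}
    return min(fits, key=lambda p: fits[p].diagnostics["aic"])


def yule_walker_autocorrelations(coeffs) -> np.ndarray:
    """Stationary autocorrelations r_1..r_P solving the Yule-Walker system.

    For each k: ``r_k = sum_j rho_j r_{|k-j|}`` with ``r_0 = 1``.
    """
    rho = np.asarray(coeffs, dtype=float)
    P = len(rho)
    if P == 0:
        return np.zeros(0)
    A = np.eye(P)
    b = np.zeros(P)
    for k in range(1, P + 1):
        for j in range(1, P + 1):
            idx = abs(k - j)
            if idx == 0:
                b[k - 1] += rho[j - 1]
            else:
                A[k - 1, idx - 1] -= rho[j - 1]
    return np.linalg.solve(A, b)


def stationary_moments(fit: ARFit) -> tuple[float, float]:
    """Stationary mean and standard deviation in closed form.

    ``mu = rho_0 / (1 - sum rho_j)``;
    ``sigma^2 = sigma_xi^2 / (1 - sum_j rho_j r_j)`` with the Yule-Walker
    autocorrelations ``r_j``.
    """
    if not fit.is_stationary:
        raise NonstationaryError(f"AR coefficients {fit.coeffs} are nonstationary")
    rho_sum = sum(fit.coeffs)
    mu = fit.intercept / (1.0 - rho_sum)
    r = yule_walker_autocorrelations(fit.coeffs)
    denom = 1.0 - float(np.dot(fit.coeffs, r))
    if denom <= 0:
        raise NonstationaryError("Yule-Walker variance denominator is non-positive")
    sigma = fit.innovation_sd / math.sqrt(denom)
    return mu, sigma


def calibrate_intercept_ar(fit: ARFit, target_mean: float) -> ARFit:
    """Fit with intercept ``rho_0 = (1 - sum rho_j) * target_mean``."""
    rho_sum = sum(fit.coeffs)
    if rho_sum >= 1.0:
        raise NonstationaryError("sum of AR coefficients >= 1; cannot calibrate mean")
    return replace(fit, intercept=(1.0 - rho_sum) * float(target_mean))


def rescale_innovation_sd(fit: ARFit, target_sd: float) -> ARFit:
    """Fit whose stationary sd equals ``target_sd`` (coefficients unchanged)."""
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    if target_sd == 0.0:
        return replace(fit, innovation_sd=0.0)
    _, sd = stationary_moments(fit)
    if sd == 0.0:
        r = yule_walker_autocorrelations(fit.coeffs)
        denom = 1.0 - float(np.dot(fit.coeffs, r))
        return replace(fit, innovation_sd=float(target_sd) * math.sqrt(denom))
    return replace(fit, innovation_sd=fit.innovation_sd * float(target_sd) / sd)


def simulate_growth_paths(
    fit: ARFit,
    n_runs: int,
    T: int,
    burn_in: int = 500,
    shocks: ShockSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate ``n_runs`` stationary growth paths of length ``T`` (percent p.a.).

    Paths start at the stationary mean; ``burn_in`` initial years are
    discarded so the variance reaches its stationary level.  Returns an
    ``(n_runs, T)`` array.
    """
    if T < 1 or n_runs < 1:
        raise ValueError("T and n_runs must be >= 1")
    if not fit.is_stationary:
        raise NonstationaryError("refusing to simulate a nonstationary AR process")
    shocks = shocks or ShockSpec()
    if rng is None:
        rng = np.random.default_rng(shocks.seed)
    mu, _ = stationary_moments(fit)
    total = burn_in + T
    eps = shocks.draw(rng, fit.innovation_sd, (n_runs, total))
    if fit.order == 0:
        dev = eps
    else:
        # deviation-from-mean recursion as an IIR filter (zero initial state = mean start)
        a = np.concatenate([[1.0], -np.asarray(fit.coeffs)])
        dev = signal.lfilter([1.0], a, eps, axis=-1)
    return mu + dev[:, burn_in:]


def simulate_carbon(
    fit: ARFit,
    shocks: ShockSpec | None = None,
    T: int = 63,
    burn_in: int = 500,
    start_year: int = 1960,
    rng: np.random.Generator | None = None,
) -> CarbonSeries:
    """Single seeded, reproducible growth path as a :class:`CarbonSeries`."""
    path = simulate_growth_paths(fit, 1, T, burn_in=burn_in, shocks=shocks, rng=rng)[0]
    years = np.arange(start_year, start_year + T)
    return CarbonSeries(years=years, growth=path)


def bootstrap_moments(series: CarbonSeries, reps: int = 1000, seed: int | None = None):
    """95% percentile CIs for mean/sd/skewness/kurtosis under iid resampling.

    Kurtosis is plain (non-excess).  Returns a DataFrame indexed by statistic
    with columns ``point``, ``lower``, ``upper``.
    """
    import pandas as pd

    if reps < 100:
        raise ValueError("reps must be >= 100")
    x = series.growth
    n = len(x)
    if n < 10:
        raise ValueError("series too short to bootstrap (need >= 10)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    samples = x[idx]

    def _stats(arr, axis):
        mean = arr.mean(axis=axis)
        sd = arr.std(axis=axis, ddof=1)
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # constant resamples
            skew = stats.skew(arr, axis=axis)
            kurt = stats.kurtosis(arr, axis=axis, fisher=False)
        return np.stack([mean, sd, np.nan_to_num(skew), np.nan_to_num(kurt, nan=0.0)])

    point = _stats(x, axis=0)
    boot = _stats(samples, axis=1)
    lower = np.percentile(boot, 2.5, axis=1)
    upper = np.percentile(boot, 97.5, axis=1)
    return pd.DataFrame(
        {"point": point, "lower": lower, "upper": upper},
        index=["mean", "sd", "skewness", "kurtosis"],
    )
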