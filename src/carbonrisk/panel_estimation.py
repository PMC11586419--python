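"""Dynamic panel logit estimation on a country-year disaster panel.

The design regresses the one-year-ahead binary disaster state on current and
lagged global CO2 growth, the log urban population share, the lagged observed
state and optional country / year dummy fixed effects.  Estimation is
maximum likelihood via statsmodels; classification skill is evaluated with a
Mann-Whitney AUROC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .carbon_dynamics import CarbonSeries
from .model_core import LogitParams

__all__ = [
    "DisasterPanel",
    "PanelDesign",
    "LogitFit",
    "SeparationError",
    "build_design",
    "fit_panel_logit",
    "auroc",
    "pseudo_r2",
]

FE_MODES = ("none", "one_way", "two_way")


class SeparationError(ValueError):
    """Outcomes are perfectly separable; ML estimates do not exist."""


@dataclass(frozen=True)
class DisasterPanel:
    """Country-year panel of binary disaster states with an urban-share covariate.

    ``frame`` must contain columns ``country``, ``year``, ``event`` (binary,
    1 if at least one climate-related event that year) and ``urban_share``
    (fraction in (0, 1]).  An optional ``event_count`` column keeps raw counts;
    multiple events per country-year collapse to ``event = 1``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        required = {"country", "year", "event", "urban_share"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if df.duplicated(["country", "year"]).any():
            dupes = df[df.duplicated(["country", "year"], keep=False)]
            raise ValueError(
                f"duplicate (country, year) pairs, e.g. {dupes.iloc[0][['country', 'year']].tolist()}"
            )
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be binary 0/1")
        if "event_count" in df.columns:
            if (df["event_count"] < df["event"]).any():
                raise ValueError("event_count must be >= event")
        shares = df["urban_share"].dropna()
        if ((shares <= 0) | (shares > 1)).any():
            raise ValueError("urban_share must lie in (0, 1]")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @classmethod
    def from_counts(cls, frame: pd.DataFrame) -> "DisasterPanel":
        """Build from an ``event_count`` column, deriving the binary state."""
        df = frame.copy()
        df["event"] = (df["event_count"] > 0).astype(int)
        return cls(df)

    @property
    def countries(self) -> np.ndarray:
        return self.frame["country"].unique()

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.frame["year"].unique())

    def pooled_incidence(self) -> float:
        return float(self.frame["event"].mean())


@dataclass
class PanelDesign:
    """Assembled regression design for the dynamic panel logit."""

    X: pd.DataFrame
    y: pd.Series
    countries: pd.Series
    outcome_years: pd.Series
    lag_order: int
    fe: str
    lag_cols: tuple[str, ...]
    control_cols: tuple[str, ...]
    dropped_rows: int = 0
    excluded_countries: tuple = ()
    flagged_years: tuple = ()

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class LogitFit:
    """Dynamic panel logit fit: parameters, covariance and diagnostics."""

    params: LogitParams
    covariance: pd.DataFrame
    standard_errors: pd.Series
    pseudo_r2: float
    auroc: float
    n_obs: int
    converged: bool
    loglik: float
    loglik_null: float
    fitted_probs: np.ndarray = field(repr=False, default=None)
    coef_table: pd.DataFrame = field(repr=False, default=None)


def build_design(
    panel: DisasterPanel,
    carbon: CarbonSeries,
    lag_order: int = 3,
    fe: str = "none",
    lagged_state: bool = True,
) -> PanelDesign:
    """Assemble the regression design with outcome ``s_{i,t+1}``.

    Regressors for outcome year ``y`` are the global growth rates
    ``c_{y-1} .. c_{y-1-P}``, the country's log urban share and lagged state at
    ``y-1``, plus fixed-effect dummies.  The first ``P + 1`` panel years are
    dropped by lag construction; rows with missing covariates are dropped with
    a logged count.  Under country fixed effects, countries whose outcomes are
    all zero or all one are excluded (their dummies perfectly separate).
    """
    if lag_order < 0:
        raise ValueError("lag_order must be >= 0")
    if fe not in FE_MODES:
        raise ValueError(f"fe must be one of {FE_MODES}")

    growth_by_year = dict(zip(carbon.years.tolist(), carbon.growth.tolist()))
    df = panel.frame.sort_values(["country", "year"]).copy()
    df["lag_event"] = df.groupby("country")["event"].shift(1)
    df["lag_urban"] = df.groupby("country")["urban_share"].shift(1)
    df["lag_year_ok"] = df.groupby("country")["year"].diff() == 1

    # outcome year y regresses on information dated y-1
    min_outcome = int(df["year"].min()) + lag_order + 1
    rows = df[(df["year"] >= min_outcome) & df["lag_year_ok"]].copy()
    for j in range(lag_order + 1):
        rows[f"c_lag{j}"] = rows["year"].map(
            lambda y, j=j: growth_by_year.get(y - 1 - j, np.nan)
        )
    rows["log_urban"] = np.log(rows["lag_urban"])

    lag_cols = tuple(f"c_lag{j}" for j in range(lag_order + 1))
    control_cols = ("log_urban",)
    needed = list(lag_cols) + list(control_cols) + (["lag_event"] if lagged_state else [])
    before = len(rows)
    rows = rows.dropna(subset=needed)
    dropped = before - len(rows)
    if rows.empty:
        raise ValueError("no rows survive lag construction; check carbon coverage")

    excluded: tuple = ()
    if fe in ("one_way", "two_way"):
        by_country = rows.groupby("country")["event"].agg(["mean"])
        degenerate = by_country[(by_country["mean"] == 0.0) | (by_country["mean"] == 1.0)]
        excluded = tuple(degenerate.index)
        if excluded:
            rows = rows[~rows["country"].isin(excluded)]

    flagged_years: tuple = ()
    if fe == "two_way":
        by_year = rows.groupby("year")["event"].mean()
        flagged_years = tuple(by_year[(by_year == 0.0) | (by_year == 1.0)].index)

    X = pd.DataFrame({"const": 1.0}, index=rows.index)
    for col in lag_cols:
        X[col] = rows[col]
    X["log_urban"] = rows["log_urban"]
    if lagged_state:
        X["lag_event"] = rows["lag_event"].astype(float)
    if fe in ("one_way", "two_way"):
        X = pd.concat(
            [X, pd.get_dummies(rows["country"], prefix="country", drop_first=True, dtype=float)],
            axis=1,
        )
    if fe == "two_way":
        X = pd.concat(
            [X, pd.get_dummies(rows["year"], prefix="year", drop_first=True, dtype=float)],
            axis=1,
        )

    return PanelDesign(
        X=X,
        y=rows["event"].astype(float),
        countries=rows["country"],
        outcome_years=rows["year"],
        lag_order=lag_order,
        fe=fe,
        lag_cols=lag_cols,
        control_cols=control_cols,
        dropped_rows=dropped,
        excluded_countries=excluded,
        flagged_years=flagged_years,
    )


def _extract_params(design: PanelDesign, estimates: pd.Series) -> LogitParams:
    country_effects = {
        name.removeprefix("country_"): float(v)
        for name, v in estimates.items()
        if name.startswith("country_")
    }
    time_effects = {
        int(name.removeprefix("year_")): float(v)
        for name, v in estimates.items()
        if name.startswith("year_")
    }
    return LogitParams(
        intercept=float(estimates["const"]),
        lag_coeffs=tuple(float(estimates[c]) for c in design.lag_cols),
        control_coeffs=tuple(float(estimates[c]) for c in design.control_cols if c in estimates),
        persistence=float(estimates.get("lag_event", 0.0)),
        country_effects=country_effects,
        time_effects=time_effects,
    )


def fit_panel_logit(
    design: PanelDesign, cluster_robust: bool = False, maxiter: int = 200
) -> LogitFit:
    """Maximum-likelihood fit of the dynamic panel logit.

    ``cluster_robust=True`` clusters the coefficient covariance by country;
    the default is the classical ML covariance.  Perfect separation raises
    :class:`SeparationError` naming the offending groups; non-convergence is
    flagged on the result, never silent.
    """
    y = design.y.to_numpy()
    if y.min() == y.max():
        raise SeparationError("outcomes are single-class; logit undefined")

    model = sm.Logit(y, design.X.to_numpy())
    fit_kwargs = {"disp": 0, "maxiter": maxiter}
    if cluster_robust:
        fit_kwargs["cov_type"] = "cluster"
        fit_kwargs["cov_kwds"] = {"groups": pd.factorize(design.countries)[0]}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            result = model.fit(**fit_kwargs)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        groups = list(design.excluded_countries) + list(design.flagged_years)
        raise SeparationError(
            f"perfect separation in panel logit (flagged groups: {groups or 'none recorded'})"
        ) from exc

    cols = list(design.X.columns)
    estimates = pd.Series(result.params, index=cols)
    cov = pd.DataFrame(result.cov_params(), index=cols, columns=cols)
    se = pd.Series(np.sqrt(np.diag(cov)), index=cols)
    probs = np.asarray(result.predict())
    converged = bool(result.mle_retvals.get("converged", True))

    zvals = estimates / se
    coef_table = pd.DataFrame(
        {
            "term": cols,
            "estimate": estimates.to_numpy(),
            "se": se.to_numpy(),
            "z": zvals.to_numpy(),
            "p": 2.0 * (1.0 - _normal_cdf(np.abs(zvals.to_numpy()))),
        }
    )

    return LogitFit(
        params=_extract_params(design, estimates),
        covariance=cov,
        standard_errors=se,
        pseudo_r2=pseudo_r2(result.llf, result.llnull),
        auroc=auroc(probs, y),
        n_obs=design.n_obs,
        converged=converged,
        loglik=float(result.llf),
        loglik_null=float(result.llnull),
        fitted_probs=probs,
        coef_table=coef_table,
    )


def _normal_cdf(z):
    from scipy.special import ndtr

    return ndtr(z)


def auroc(scores, outcomes) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Fraction of (positive, negative) pairs where the positive scores higher,
    ties counted one half.  Computed via average ranks in O(n log n); requires
    at least one positive and one negative outcome.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must align")
    pos = outcomes == 1
    n_pos = int(pos.sum())
    n_neg = len(outcomes) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined for single-class outcomes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pseudo_r2(loglik: float, loglik_null: float) -> float:
    """McFadden pseudo R-squared, ``1 - l / l0``."""
    if loglik_null == 0.0:
        raise ValueError("null log-likelihood of zero; pseudo R2 undefined")
    if not (math.isfinite(loglik) and math.isfinite(loglik_null)):
        raise ValueError("log-likelihoods must be finite")
    return 1.0 - loglik / loglik_null
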