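"""Synthetic fixtures emulating the disaster-panel / CO2-growth input structure.

Generates (i) annual CO2 growth histories from the stationary AR process and
(ii) country-year disaster panels drawn from the logistic transfer with
country effects, persistence dynamics and shared carbon forcing -- so the
whole pipeline is testable without any external download.  All generators
are pure functions of their seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import presets
from .carbon_dynamics import ARFit, CarbonSeries, ar_fit_from_coeffs, simulate_growth_paths
from .model_core import LogitParams
from .panel_estimation import DisasterPanel

__all__ = [
    "PanelGeneratorSpec",
    "default_carbon_process",
    "generate_carbon_history",
    "generate_panel",
    "write_fixtures",
]

#: Approximate 1960 atmospheric CO2 level used to anchor synthetic ppm tracks.
LEVEL_ANCHOR_PPM = 316.9


def default_carbon_process() -> ARFit:
    """Stationary AR(3) with the published coefficients, mean-calibrated."""
    return ar_fit_from_coeffs(
        presets.AR3_RHO, presets.AR3_SIGMA_XI, mean=presets.BASELINE_MU_C
    )


def generate_carbon_history(
    process: ARFit | None = None,
    years: int = 63,
    seed: int | None = 0,
    start_year: int = 1960,
    burn_in: int = 500,
    with_levels: bool = True,
) -> CarbonSeries:
    """Annual CO2 growth series with the stationary population moments.

    Defaults to 63 observations from the published AR(3) process.  When
    ``with_levels`` an integrated ppm level track is attached (anchored at
    ``LEVEL_ANCHOR_PPM``).
    """
    process = process or default_carbon_process()
    rng = np.random.default_rng(seed)
    growth = simulate_growth_paths(process, 1, years, burn_in=burn_in, rng=rng)[0]
    levels = None
    if with_levels:
        levels = LEVEL_ANCHOR_PPM * np.exp(np.cumsum(growth) / 100.0)
    return CarbonSeries(
        years=np.arange(start_year, start_year + years), growth=growth, levels=levels
    )


@dataclass(frozen=True)
class PanelGeneratorSpec:
    """Specification of a synthetic disaster panel.

    Country effects are Normal(0, ``country_effect_sd``) on the log-odds
    scale; urban shares follow deterministic per-country logistic growth
    curves bounded in (0, 1); carbon forcing is shared across countries.
    When ``target_incidence`` is set the intercept is calibrated so the
    model-implied pooled incidence matches it; otherwise ``params.intercept``
    is used verbatim.
    """

    n_countries: int = 200
    start_year: int = 1960
    end_year: int = 2022
    params: LogitParams = field(
        default_factory=lambda: presets.LOGIT_ESTIMATES[("one_way", "urban")]
    )
    country_effect_sd: float = 0.5
    carbon: ARFit | CarbonSeries | None = None
    target_incidence: float | None = presets.BASELINE_INCIDENCE
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")


def _urban_curves(rng: np.random.Generator, n: int, years: np.ndarray) -> np.ndarray:
    """Deterministic per-country logistic urbanisation curves, (n, len(years))."""
    lo = rng.uniform(0.05, 0.35, size=n)
    hi = rng.uniform(0.55, 0.95, size=n)
    rate = rng.uniform(0.02, 0.09, size=n)
    midpoint = rng.uniform(years[0], years[-1], size=n)
    t = years[None, :] - midpoint[:, None]
    return lo[:, None] + (hi - lo)[:, None] * expit(rate[:, None] * t)


def generate_panel(
    spec: PanelGeneratorSpec, return_details: bool = False
) -> DisasterPanel | tuple[DisasterPanel, dict]:
    """Draw a binary disaster panel from the logistic transfer model.

    Events for year ``y`` use carbon lags ``c_{y-1-j}``, log urban share and
    the lagged drawn state at ``y-1``, plus the country's log-odds effect --
    mirroring the estimation design.  With ``return_details`` the calibrated
    intercept, country effects and carbon series are also returned.
    """
    params = spec.params
    P = params.lag_order
    years = np.arange(spec.start_year, spec.end_year + 1)
    n_years = len(years)
    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    rng_carbon, rng_struct, rng_events = (np.random.default_rng(s) for s in seeds)

    # carbon history must cover lags back to start_year - 1 - P
    carbon_start = spec.start_year - 1 - P
    if isinstance(spec.carbon, CarbonSeries):
        carbon = spec.carbon
        missing = [y for y in range(carbon_start, spec.end_year) if y not in set(carbon.years.tolist())]
        if missing:
            raise ValueError(f"supplied carbon series missing years {missing[:5]}...")
    else:
        process = spec.carbon or default_carbon_process()
        n_carbon = spec.end_year - carbon_start
        growth = simulate_growth_paths(process, 1, n_carbon, rng=rng_carbon)[0]
        carbon = CarbonSeries(years=np.arange(carbon_start, spec.end_year), growth=growth)
    growth_by_year = dict(zip(carbon.years.tolist(), carbon.growth.tolist()))

    effects = rng_struct.normal(0.0, spec.country_effect_sd, size=spec.n_countries)
    urban = _urban_curves(rng_struct, spec.n_countries, years)  # (n, n_years)

    h = np.asarray(params.lag_coeffs)
    carbon_term = np.array(
        [sum(h[j] * growth_by_year[y - 1 - j] for j in range(P + 1)) for y in years]
    )
    gamma = params.control_coeffs[0] if params.control_coeffs else 0.0
    # covariate enters lagged; approximate the first year's lag with its own value
    log_urban_lag = np.log(np.column_stack([urban[:, :1], urban[:, :-1]]))
    base_no_intercept = carbon_term[None, :] + gamma * log_urban_lag + effects[:, None]
    delta = params.persistence
    anchor = spec.target_incidence if spec.target_incidence is not None else 0.062

    def pooled_probability(h_bar: float) -> float:
        # deterministic probability recursion (state replaced by its expectation)
        q = np.full(spec.n_countries, anchor)
        total = 0.0
        for k in range(n_years):
            q = expit(h_bar + base_no_intercept[:, k] + delta * q)
            total += q.mean()
        return total / n_years

    if spec.target_incidence is not None:
        target = spec.target_incidence
        if not 0.0 < target < 1.0:
            raise ValueError("target_incidence must be in (0, 1)")
        center = float(logit(target))
        lo, hi = center - 15.0, center + 15.0
        try:
            h_bar = brentq(lambda b: pooled_probability(b) - target, lo, hi, xtol=1e-10)
        except ValueError as exc:
            raise ValueError(
                f"target incidence {target} unreachable for the supplied coefficients"
            ) from exc
    else:
        h_bar = params.intercept

    state = (rng_events.random(spec.n_countries) < anchor).astype(float)
    events = np.empty((spec.n_countries, n_years), dtype=int)
    probs = np.empty((spec.n_countries, n_years))
    for k in range(n_years):
        p = expit(h_bar + base_no_intercept[:, k] + delta * state)
        draws = (rng_events.random(spec.n_countries) < p).astype(int)
        events[:, k] = draws
        probs[:, k] = p
        state = draws.astype(float)

    frame = pd.DataFrame(
        {
            "country": np.repeat([f"C{i:03d}" for i in range(spec.n_countries)], n_years),
            "year": np.tile(years, spec.n_countries),
            "event": events.ravel(),
            "event_count": events.ravel(),
            "urban_share": urban.ravel(),
        }
    )
    panel = DisasterPanel(frame)
    if not return_details:
        return panel
    details = {
        "intercept": float(h_bar),
        "country_effects": {f"C{i:03d}": float(e) for i, e in enumerate(effects)},
        "carbon": carbon,
        "model_probs": probs,
        "implied_pooled_incidence": float(probs.mean()),
    }
    return panel, details


def write_fixtures(out_dir, spec: PanelGeneratorSpec | None = None) -> dict:
    """Write a seeded carbon series, panel and manifest; return the manifest.

    Three files: ``carbon.csv``, ``panel.csv`` and ``manifest.yaml`` (seeds
    and true parameters, round-trippable through the config reader).
    Re-running with the same spec produces byte-identical data files.
    """
    from pathlib import Path

    from . import io as crio

    spec = spec or PanelGeneratorSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel, details = generate_panel(spec, return_details=True)
    carbon = details["carbon"]
    # attach an integrated level track anchored so 1960 is near the observed record
    levels = LEVEL_ANCHOR_PPM * np.exp(np.cumsum(carbon.growth) / 100.0)
    carbon = CarbonSeries(years=carbon.years, growth=carbon.growth, levels=levels)

    carbon_path = out / "carbon.csv"
    panel_path = out / "panel.csv"
    manifest_path = out / "manifest.yaml"
    crio.write_carbon_csv(carbon, carbon_path)
    crio.write_panel_csv(panel, panel_path)

    true_params = LogitParams(
        intercept=details["intercept"],
        lag_coeffs=spec.params.lag_coeffs,
        control_coeffs=spec.params.control_coeffs,
        persistence=spec.params.persistence,
    )
    manifest = {
        "seed": spec.seed,
        "n_countries": spec.n_countries,
        "start_year": spec.start_year,
        "end_year": spec.end_year,
        "country_effect_sd": spec.country_effect_sd,
        "target_incidence": spec.target_incidence,
        "true_params": crio.params_to_dict(true_params),
        "files": {"carbon": carbon_path.name, "panel": panel_path.name},
    }
    crio.dump_yaml(manifest, manifest_path)
    return manifest
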