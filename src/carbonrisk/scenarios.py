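"""Disaster-risk evaluation under IPCC RCP concentration pathways.

Each scenario fixes a mean CO2 growth rate (and a stationary volatility
regime); the calibrated transfer is re-evaluated at the scenario mean for the
certainty equivalent, and the AR process is re-centred/re-scaled for the
stochastic simulation.  Discrete "decarbonisation dividend" gradients compare
pathways against a reference scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd

from . import presets
from .carbon_dynamics import ARFit, calibrate_intercept_ar, rescale_innovation_sd
from .model_core import (
    LogitParams,
    TransferPoint,
    calibrated_params,
    certainty_equivalent,
)
from .monte_carlo import SimulationConfig, SimulationSummary, simulate_incidence

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "named_scenarios",
    "mean_growth_from_endpoint",
    "scenario_certainty_equivalent",
    "scenario_simulation",
    "evaluate_scenarios",
    "decarbonisation_gradient",
]

SIGMA_REGIMES = {"baseline": presets.BASELINE_SIGMA_C, "min": presets.SIGMA_C_MIN}


@dataclass(frozen=True)
class ScenarioSpec:
    """One concentration pathway: name, mean growth and volatility (percent p.a.)."""

    name: str
    mu_c: float
    sigma_c: float = presets.BASELINE_SIGMA_C
    end_level_ppm: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.mu_c):
            raise ValueError("mu_c must be finite")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")


@dataclass
class ScenarioResult:
    """Certainty-equivalent and simulated risk for one pathway."""

    spec: ScenarioSpec
    certainty_equivalent: float
    summaries: dict[str, SimulationSummary] = field(default_factory=dict)


def named_scenarios(sigma_c: float = presets.BASELINE_SIGMA_C) -> list[ScenarioSpec]:
    """The five named RCP pathways at a common volatility."""
    return [ScenarioSpec(name=n, mu_c=m, sigma_c=sigma_c) for n, m in presets.RCP_MU_C.items()]


def mean_growth_from_endpoint(c_start: float, c_end: float, years: int) -> float:
    """Mean annual log growth (percent p.a.) reaching ``c_end`` from ``c_start``."""
    if c_start <= 0 or c_end <= 0:
        raise ValueError("concentration levels must be positive")
    if years < 1:
        raise ValueError("years must be >= 1")
    return 100.0 * math.log(c_end / c_start) / years


def scenario_certainty_equivalent(
    spec: ScenarioSpec, params: LogitParams, point: TransferPoint
) -> float:
    """Certainty equivalent at the scenario mean, non-carbon terms held fixed.

    ``params`` must carry an intercept calibrated at the baseline ``point``;
    only ``mu_c`` is varied.  Returns a fraction.
    """
    if not params.is_calibrated:
        raise ValueError("params must be calibrated at the baseline point first")
    return certainty_equivalent(params, replace(point, mu_c=spec.mu_c))


def scenario_simulation(
    spec: ScenarioSpec,
    params: LogitParams,
    point: TransferPoint,
    ar_template: ARFit,
    config: SimulationConfig | None = None,
    **config_overrides,
) -> ScenarioResult:
    """Simulate stochastic incidence for one scenario.

    The AR intercept is re-centred to ``spec.mu_c`` and the innovation sd
    rescaled so the stationary sd equals ``spec.sigma_c`` (coefficients kept).
    The transfer intercept is recalibrated so the scenario certainty
    equivalent is an exact fixed point of the persistence recursion, which
    makes the ``sigma_c = 0`` limit degenerate at the certainty equivalent.
    """
    ce = scenario_certainty_equivalent(spec, params, point)
    ar = rescale_innovation_sd(calibrate_intercept_ar(ar_template, spec.mu_c), spec.sigma_c)
    scen_point = replace(point, mu_c=spec.mu_c, lagged_incidence=ce)
    scen_params = calibrated_params(params, scen_point, ce)
    if config is None:
        config = SimulationConfig(params=scen_params, point=scen_point, carbon=ar)
    else:
        config = replace(config, params=scen_params, point=scen_point, carbon=ar)
    if config_overrides:
        config = replace(config, **config_overrides)
    label = f"sigma={spec.sigma_c:g}"
    result = simulate_incidence(config)
    return ScenarioResult(
        spec=spec, certainty_equivalent=ce, summaries={label: result.summary}
    )


def evaluate_scenarios(
    specs: list[ScenarioSpec],
    params: LogitParams,
    point: TransferPoint,
    ar_template: ARFit,
    config: SimulationConfig | None = None,
    **config_overrides,
) -> dict[str, ScenarioResult]:
    """Run every scenario, merging results of different sigma regimes per name."""
    results: dict[str, ScenarioResult] = {}
    for spec in specs:
        res = scenario_simulation(spec, params, point, ar_template, config, **config_overrides)
        if spec.name in results:
            results[spec.name].summaries.update(res.summaries)
        else:
            results[spec.name] = res
    return results


def decarbonisation_gradient(
    results: Mapping[str, ScenarioResult], reference: str = "RCP2.6"
) -> pd.DataFrame:
    """Discrete gradients of risk with respect to mean growth vs a reference.

    For each non-reference scenario s:
    ``(value(s) - value(ref)) / (mu_c(s) - mu_c(ref))`` for the certainty
    equivalent and every simulated mean regime, computed from unrounded
    internal values (percent scale).  The reference row is NaN.
    """
    if reference not in results:
        raise KeyError(f"reference scenario {reference!r} not in results")
    ref = results[reference]
    records = []
    for name, res in results.items():
        row: dict = {"scenario": name, "mu_c": res.spec.mu_c}
        if name == reference:
            row["dmu_p_bar"] = float("nan")
            for label in res.summaries:
                row[f"dmean[{label}]"] = float("nan")
        else:
            dmu = res.spec.mu_c - ref.spec.mu_c
            if dmu == 0.0:
                row["dmu_p_bar"] = float("nan")
            else:
                row["dmu_p_bar"] = (
                    100.0 * (res.certainty_equivalent - ref.certainty_equivalent) / dmu
                )
            for label, summary in res.summaries.items():
                ref_summary = ref.summaries.get(label)
                if ref_summary is None or dmu == 0.0:
                    row[f"dmean[{label}]"] = float("nan")
                else:
                    row[f"dmean[{label}]"] = (
                        100.0 * (summary.mean.point - ref_summary.mean.point) / dmu
                    )
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("scenario")


def scenario_table(results: Mapping[str, ScenarioResult]) -> pd.DataFrame:
    """Tidy per-scenario table (percent scale) for reporting."""
    records = []
    for name, res in results.items():
        for label, s in res.summaries.items():
            records.append(
                {
                    "scenario": name,
                    "regime": label,
                    "mu_c": res.spec.mu_c,
                    "certainty_equivalent_pct": 100.0 * res.certainty_equivalent,
                    "mean_lower_pct": 100.0 * s.mean.lower,
                    "mean_upper_pct": 100.0 * s.mean.upper,
                    "wedge_lower_pct": 100.0 * s.expected_wedge.lower,
                    "wedge_upper_pct": 100.0 * s.expected_wedge.upper,
                    "sd_lower_pct": 100.0 * s.sd.lower,
                    "sd_upper_pct": 100.0 * s.sd.upper,
                    "skew_lower": s.skewness.lower,
                    "skew_upper": s.skewness.upper,
                    "kurt_lower": s.kurtosis.lower,
                    "kurt_upper": s.kurtosis.upper,
                }
            )
    return pd.DataFrame.from_records(records)
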