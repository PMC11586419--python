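import numpy as np
import pytest

from carbonrisk import presets
from carbonrisk.panel_estimation import build_design, fit_panel_logit
from carbonrisk.synthetic_data import PanelGeneratorSpec, default_carbon_process, generate_panel


@pytest.fixture(scope="session")
def one_way_calibrated():
    """Published one-way urban estimates calibrated at the historical baseline."""
    return presets.baseline_calibrated("one_way", "urban")


@pytest.fixture(scope="session")
def ar3_process():
    return default_carbon_process()


@pytest.fixture(scope="session")
def recovery_study():
    """Shared parameter-recovery study on synthetic panels.

    Experiment A: 50 seeded one-way FE fits at the published one-way urban
    operating point (150 countries) -- records lag-coefficient signs, AUROC
    and the fits themselves.
    Experiment B: 50 seeded no-FE fits with zero country effects -- records
    95% CI coverage per coefficient against the known truth.
    Scaled down from 200 countries to keep the suite within budget.
    """
    sign_ok = []
    aurocs = []
    first_fit = None
    first_panel = None
    first_details = None
    for rep in range(50):
        spec = PanelGeneratorSpec(n_countries=150, seed=1000 + rep)
        panel, det = generate_panel(spec, return_details=True)
        design = build_design(panel, det["carbon"], lag_order=3, fe="one_way")
        fit = fit_panel_logit(design)
        sign_ok.append(all(h > 0 for h in fit.params.lag_coeffs))
        aurocs.append(fit.auroc)
        if rep == 0:
            first_fit, first_panel, first_details = fit, panel, det

    true = presets.LOGIT_ESTIMATES[("none", "urban")]
    names = ["const", "c_lag0", "c_lag1", "c_lag2", "c_lag3", "log_urban", "lag_event"]
    coverage = np.zeros(len(names))
    for rep in range(50):
        spec = PanelGeneratorSpec(
            n_countries=200, params=true, country_effect_sd=0.0, seed=2000 + rep
        )
        panel, det = generate_panel(spec, return_details=True)
        design = build_design(panel, det["carbon"], lag_order=3, fe="none")
        fit = fit_panel_logit(design)
        truth = [det["intercept"], *true.lag_coeffs, true.control_coeffs[0], true.persistence]
        est = [
            fit.params.intercept,
            *fit.params.lag_coeffs,
            fit.params.control_coeffs[0],
            fit.params.persistence,
        ]
        for i, name in enumerate(names):
            if abs(est[i] - truth[i]) <= 1.96 * float(fit.standard_errors[name]):
                coverage[i] += 1

    return {
        "n_reps": 50,
        "sign_ok": sign_ok,
        "aurocs": aurocs,
        "coverage": dict(zip(names, coverage)),
        "first_fit": first_fit,
        "first_panel": first_panel,
        "first_details": first_details,
    }
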