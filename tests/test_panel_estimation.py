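import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from carbonrisk.carbon_dynamics import CarbonSeries
from carbonrisk.panel_estimation import (
    DisasterPanel,
    SeparationError,
    auroc,
    build_design,
    fit_panel_logit,
    pseudo_r2,
)
from carbonrisk.synthetic_data import PanelGeneratorSpec, generate_panel


def _toy_panel(n_countries=5, start=1960, end=2022, seed=0, p=0.3):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_countries):
        for y in range(start, end + 1):
            rows.append(
                {
                    "country": f"C{i}",
                    "year": y,
                    "event": int(rng.random() < p),
                    "urban_share": 0.5,
                }
            )
    return DisasterPanel(pd.DataFrame(rows))


def _toy_carbon(start=1955, end=2022, seed=0):
    rng = np.random.default_rng(seed)
    years = np.arange(start, end + 1)
    return CarbonSeries(years=years, growth=rng.normal(1.6, 0.7, size=len(years)))


class TestDisasterPanel:
    def test_duplicate_keys_rejected(self):
        df = pd.DataFrame(
            {
                "country": ["A", "A"],
                "year": [2000, 2000],
                "event": [0, 1],
                "urban_share": [0.5, 0.5],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            DisasterPanel(df)

    def test_nonbinary_event_rejected(self):
        df = pd.DataFrame(
            {"country": ["A"], "year": [2000], "event": [2], "urban_share": [0.5]}
        )
        with pytest.raises(ValueError, match="binary"):
            DisasterPanel(df)

    def test_urban_share_range(self):
        df = pd.DataFrame(
            {"country": ["A"], "year": [2000], "event": [1], "urban_share": [1.5]}
        )
        with pytest.raises(ValueError, match="urban_share"):
            DisasterPanel(df)

    def test_from_counts_collapses_to_binary(self):
        df = pd.DataFrame(
            {"country": ["A", "A"], "year": [2000, 2001], "event_count": [3, 0], "urban_share": [0.5, 0.5]}
        )
        panel = DisasterPanel.from_counts(df)
        assert panel.frame["event"].tolist() == [1, 0]


class TestBuildDesign:
    def test_lag_bookkeeping_1960_2022(self):
        panel = _toy_panel()
        carbon = _toy_carbon()
        design = build_design(panel, carbon, lag_order=3, fe="none")
        # outcome years 1964..2022, regressors dated 1963..2021 with lags to 1960
        assert design.outcome_years.min() == 1964
        assert design.outcome_years.max() == 2022
        assert design.n_obs == 5 * 59
        growth = dict(zip(carbon.years.tolist(), carbon.growth.tolist()))
        row = design.X[design.outcome_years == 1970].iloc[0]
        for j in range(4):
            assert row[f"c_lag{j}"] == pytest.approx(growth[1969 - j])

    def test_two_way_dummy_count(self):
        panel = _toy_panel()
        design = build_design(panel, _toy_carbon(), lag_order=3, fe="two_way")
        n_countries = design.countries.nunique()
        n_years = design.outcome_years.nunique()
        n_dummies = sum(c.startswith(("country_", "year_")) for c in design.X.columns)
        assert n_dummies == (n_countries - 1) + (n_years - 1)

    def test_all_zero_country_excluded_under_fe(self):
        panel = _toy_panel()
        df = panel.frame.copy()
        df.loc[df["country"] == "C0", "event"] = 0
        panel = DisasterPanel(df)
        design = build_design(panel, _toy_carbon(), lag_order=3, fe="one_way")
        assert "C0" in design.excluded_countries
        assert design.n_obs == 4 * 59

    def test_negative_lag_order_rejected(self):
        with pytest.raises(ValueError):
            build_design(_toy_panel(), _toy_carbon(), lag_order=-1)

    def test_missing_covariate_rows_dropped_with_count(self):
        panel = _toy_panel()
        df = panel.frame.copy()
        df.loc[(df["country"] == "C1") & (df["year"] == 1999), "urban_share"] = np.nan
        design = build_design(DisasterPanel(df), _toy_carbon(), lag_order=3, fe="none")
        assert design.dropped_rows == 1  # the year-2000 row loses its lagged covariate


class TestFitPanelLogit:
    def test_single_country_matches_plain_logistic(self):
        # independent route: GLM-Binomial IRLS on the same design
        import statsmodels.api as sm

        panel = _toy_panel(n_countries=1, seed=4)
        design = build_design(panel, _toy_carbon(), lag_order=3, fe="none")
        fit = fit_panel_logit(design)
        glm = sm.GLM(
            design.y.to_numpy(), design.X.to_numpy(), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(
            np.r_[fit.params.intercept, fit.params.lag_coeffs],
            glm.params[:5],
            atol=1e-6,
        )

    def test_all_zero_outcomes_raise_separation(self):
        panel = _toy_panel(p=0.0)
        design = build_design(panel, _toy_carbon(), lag_order=3, fe="none")
        with pytest.raises(SeparationError):
            fit_panel_logit(design)

    def test_cluster_robust_changes_only_covariance(self):
        spec = PanelGeneratorSpec(n_countries=40, seed=9)
        panel, det = generate_panel(spec, return_details=True)
        design = build_design(panel, det["carbon"], lag_order=3, fe="none")
        plain = fit_panel_logit(design)
        clustered = fit_panel_logit(design, cluster_robust=True)
        np.testing.assert_allclose(plain.params.lag_coeffs, clustered.params.lag_coeffs, atol=1e-8)
        assert not np.allclose(
            plain.standard_errors.to_numpy(), clustered.standard_errors.to_numpy()
        )

    def test_invariant_to_row_order_and_relabeling(self):
        spec = PanelGeneratorSpec(n_countries=30, seed=5)
        panel, det = generate_panel(spec, return_details=True)
        design = build_design(panel, det["carbon"], lag_order=3, fe="one_way")
        fit_a = fit_panel_logit(design)

        shuffled = panel.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.copy()
        relabeled["country"] = "Z" + relabeled["country"].str.slice(1)
        design_b = build_design(
            DisasterPanel(relabeled), det["carbon"], lag_order=3, fe="one_way"
        )
        fit_b = fit_panel_logit(design_b)
        np.testing.assert_allclose(fit_a.params.lag_coeffs, fit_b.params.lag_coeffs, atol=1e-6)
        assert fit_a.auroc == pytest.approx(fit_b.auroc, abs=1e-10)


class TestAUROC:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_counted_pairs(self):
        assert auroc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_brute_force_oracle_and_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            outcomes = rng.integers(0, 2, size=n)
            if outcomes.min() == outcomes.max():
                continue
            # O(n^2) pair counting with half-credit ties
            pos = scores[outcomes == 1]
            neg = scores[outcomes == 0]
            total = 0.0
            for sp in pos:
                for sn in neg:
                    total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            expected = total / (len(pos) * len(neg))
            assert auroc(scores, outcomes) == pytest.approx(expected, abs=1e-12)
            assert auroc(scores, outcomes) == pytest.approx(
                roc_auc_score(outcomes, scores), abs=1e-12
            )


class TestPseudoR2:
    def test_null_fit_is_zero(self):
        assert pseudo_r2(-10.0, -10.0) == 0.0

    def test_hand_computed_toy(self):
        # 4 Bernoulli rows: y = (1, 0, 1, 1), fitted p = (0.8, 0.3, 0.6, 0.9)
        p = np.array([0.8, 0.3, 0.6, 0.9])
        y = np.array([1, 0, 1, 1])
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        p0 = y.mean()
        ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
        assert pseudo_r2(ll, ll0) == pytest.approx(1 - ll / ll0, abs=1e-15)
        assert 0 < pseudo_r2(ll, ll0) < 1

    def test_separable_limit_approaches_one(self):
        eps = 1e-9
        p = np.array([1 - eps, eps, 1 - eps, eps])
        y = np.array([1, 0, 1, 0])
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        ll0 = 4 * np.log(0.5)
        assert pseudo_r2(ll, ll0) > 0.999

    def test_zero_null_rejected(self):
        with pytest.raises(ValueError):
            pseudo_r2(-1.0, 0.0)


class TestParameterRecovery:
    def test_lag_signs_recovered(self, recovery_study):
        frac = np.mean(recovery_study["sign_ok"])
        assert frac >= 0.95

    def test_ci_coverage(self, recovery_study):
        n = recovery_study["n_reps"]
        for name, count in recovery_study["coverage"].items():
            assert count / n >= 0.90, f"{name}: coverage {count}/{n}"

    def test_in_sample_auroc_informative(self, recovery_study):
        assert min(recovery_study["aurocs"]) > 0.6

    def test_held_out_auroc_beats_chance(self, recovery_study):
        # refit on outcome years <= 2010, score 2011+ with the fitted params
        panel = recovery_study["first_panel"]
        det = recovery_study["first_details"]
        early = DisasterPanel(panel.frame[panel.frame["year"] <= 2010].reset_index(drop=True))
        design = build_design(early, det["carbon"], lag_order=3, fe="one_way")
        fit = fit_panel_logit(design)

        full = build_design(panel, det["carbon"], lag_order=3, fe="one_way")
        mask = (full.outcome_years > 2010).to_numpy()
        params = fit.params
        X = full.X
        scores = (
            params.intercept
            + sum(params.lag_coeffs[j] * X[f"c_lag{j}"].to_numpy() for j in range(4))
            + params.control_coeffs[0] * X["log_urban"].to_numpy()
            + params.persistence * X["lag_event"].to_numpy()
            + np.array([params.country_effect(c) for c in full.countries])
        )[mask]
        outcomes = full.y.to_numpy()[mask]
        assert auroc(scores, outcomes) > 0.5
        stat = mannwhitneyu(scores[outcomes == 1], scores[outcomes == 0], alternative="greater")
        assert stat.pvalue < 0.01
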