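import numpy as np
import pandas as pd
import pytest

from vo2verify import (adjusted_bivariate_screen, fit_logistic, hosmer_stepdown,
                       odds_ratio, pairwise_correlations)
from vo2verify.errors import ConfigurationError
from vo2verify.exhaustion import KEY_VARIABLES, OR_SCALING


def two_by_two(a, b, c, d):
    """Cohort with exposure/outcome counts a, b, c, d (exposed-positive,
    exposed-negative, unexposed-positive, unexposed-negative)."""
    exposure = [1.0] * (a + b) + [0.0] * (c + d)
    outcome = [True] * a + [False] * b + [True] * c + [False] * d
    return pd.DataFrame({"x": exposure, "leader_evaluation": outcome})


def simulate_screen_cohort(rng, n=2000, beta=None):
    """Key variables plus adjusters with a configurable true logit."""
    df = pd.DataFrame({
        "plateau_150": rng.uniform(size=n) < 0.9,
        "hrpeak": rng.normal(166, 13, n),
        "rerpeak": rng.normal(1.16, 0.10, n),
        "rpepeak": np.clip(np.round(rng.normal(17.9, 1.6, n)), 6, 20),
        "frpeak": rng.normal(40, 7.8, n),
        "age": rng.normal(59, 12, n),
        "diagnosis": rng.choice(["breast", "prostate", "colorectal"], n,
                                p=[0.79, 0.17, 0.04]),
        "vo2peak_rel": rng.normal(29.8, 7.3, n),
        "test_duration": rng.normal(9.9, 2.8, n),
    })
    beta = beta or {}
    logit = beta.get("const", -17.5)
    for var, b in beta.items():
        if var != "const":
            logit = logit + b * df[var].astype(float)
    df["leader_evaluation"] = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
    return df


class TestLogisticFit:
    def test_two_by_two_matches_cross_product(self):
        cohort = two_by_two(a=20, b=10, c=10, d=20)
        fit = fit_logistic(cohort, ["x"])
        assert np.exp(fit.coef("x")) == pytest.approx(4.0, abs=1e-6)
        orr = odds_ratio(fit, "x", model="bivariate")
        assert orr.or_value == pytest.approx(4.0, abs=1e-6)
        assert orr.ci_low < 4.0 < orr.ci_high

    def test_or_scaling_identity(self):
        rng = np.random.default_rng(5)
        df = simulate_screen_cohort(rng, n=1500,
                                    beta={"rerpeak": 7.28, "const": -8.0})
        fit = fit_logistic(df, ["rerpeak"])
        beta = fit.coef("rerpeak")
        orr = odds_ratio(fit, "rerpeak", model="bivariate")
        assert OR_SCALING["rerpeak"] == 0.10
        assert orr.or_value == pytest.approx(np.exp(0.1 * beta), rel=1e-12)

    def test_rescaling_invariance(self):
        """Expressing a variable in units k times larger scales the fitted
        coefficient by 1/k; adjusting the OR scaling unit by k leaves the
        reported odds ratio and CI unchanged (the OR refers to the same
        physical amount of the variable)."""
        rng = np.random.default_rng(6)
        df = simulate_screen_cohort(rng, n=1500,
                                    beta={"frpeak": 0.06, "const": -1.5})
        k = 10.0
        df2 = df.copy()
        df2["frpeak"] = df2["frpeak"] * k
        fit1 = fit_logistic(df, ["frpeak"])
        fit2 = fit_logistic(df2, ["frpeak"])
        o1 = odds_ratio(fit1, "frpeak", model="bivariate",
                        scaling={"frpeak": 1.0})
        o2 = odds_ratio(fit2, "frpeak", model="bivariate",
                        scaling={"frpeak": k})
        assert o2.or_value == pytest.approx(o1.or_value, abs=1e-9)
        assert o2.ci_low == pytest.approx(o1.ci_low, abs=1e-9)
        assert o2.ci_high == pytest.approx(o1.ci_high, abs=1e-9)

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "leader_evaluation": [True, True]})
        with pytest.raises(ConfigurationError):
            fit_logistic(df, ["x"])

    def test_listwise_deletion_recorded(self):
        df = two_by_two(20, 10, 10, 20)
        df.loc[0, "x"] = np.nan
        fit = fit_logistic(df, ["x"])
        assert fit.n_used == len(df) - 1

    def test_separation_flagged_not_raised(self):
        df = pd.DataFrame({"x": np.r_[np.ones(30), np.zeros(30)],
                           "leader_evaluation": [True] * 30 + [False] * 30})
        fit = fit_logistic(df, ["x"])
        assert not fit.converged

    def test_wald_ci_coverage_at_moderate_effects(self):
        """Wald CI for the OR covers the truth 95% +/- 2% at n=1000."""
        rng = np.random.default_rng(31)
        n, beta_true = 1000, 0.7
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0, 1, n)
            y = rng.uniform(size=n) < 1 / (1 + np.exp(-(0.3 + beta_true * x)))
            df = pd.DataFrame({"x": x, "leader_evaluation": y})
            fit = fit_logistic(df, ["x"])
            orr = odds_ratio(fit, "x", model="bivariate",
                             scaling={"x": 1.0})
            hits += orr.ci_low <= np.exp(beta_true) <= orr.ci_high
        assert abs(hits / reps - 0.95) < 0.02


class TestScreenAndStepdown:
    def test_null_variable_or_near_one(self):
        """A key variable independent of the outcome has OR CI covering 1.0
        at the nominal rate."""
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(100):
            df = simulate_screen_cohort(rng, n=5000, beta={"const": 1.8})
            fit = fit_logistic(df, ["rerpeak"])
            orr = odds_ratio(fit, "rerpeak", model="bivariate")
            hits += orr.ci_low <= 1.0 <= orr.ci_high
        assert hits >= 93

    def test_degenerate_entry_threshold_keeps_all(self):
        rng = np.random.default_rng(13)
        df = simulate_screen_cohort(rng, beta={"rerpeak": 7.28, "const": -8.0})
        sd = hosmer_stepdown(df, entry_p=1.0)
        assert set(sd.included) == set(KEY_VARIABLES)

    def test_no_entry_yields_explicit_empty_model(self):
        rng = np.random.default_rng(14)
        df = simulate_screen_cohort(rng, beta={"const": 1.8})
        sd = hosmer_stepdown(df, entry_p=1e-12)  # nothing can pass
        assert sd.fit is None
        assert sd.included == []
        assert set(sd.excluded) == set(KEY_VARIABLES)

    def test_active_variables_always_enter(self):
        """Strongly active variables pass the 0.25 entry screen essentially
        always; inactive ones enter at roughly the nominal false-entry rate."""
        rng = np.random.default_rng(15)
        active_in = 0
        null_entries = 0
        reps = 60
        for _ in range(reps):
            df = simulate_screen_cohort(
                rng, n=2000, beta={"rerpeak": 7.28, "rpepeak": 0.5,
                                   "const": -17.5})
            sd = hosmer_stepdown(df)
            sel = set(sd.included)
            active_in += {"rerpeak", "rpepeak"} <= sel
            null_entries += len(sel - {"rerpeak", "rpepeak"})
        assert active_in >= int(0.9 * reps)
        null_rate = null_entries / (3 * reps)
        assert null_rate < 0.40  # near the nominal 0.25 entry level

    def test_bivariate_multivariate_agree_without_confounding(self):
        """With inert adjusters, the bivariate and multivariate ORs of the
        lone active variable agree within Monte-Carlo error."""
        rng = np.random.default_rng(16)
        df = simulate_screen_cohort(rng, n=8000,
                                    beta={"rerpeak": 7.28, "const": -8.0})
        screen = adjusted_bivariate_screen(df)
        sd = hosmer_stepdown(df, screen)
        bi = screen["rerpeak"][1].or_value
        multi = next(o for o in sd.odds_ratios if o.variable == "rerpeak").or_value
        assert multi == pytest.approx(bi, rel=0.10)

    def test_diagnosis_enters_as_contrasts(self):
        rng = np.random.default_rng(18)
        df = simulate_screen_cohort(rng, beta={"rerpeak": 7.28, "const": -8.0})
        fit = fit_logistic(df, ["rerpeak", "diagnosis"])
        assert "diagnosis[prostate]" in fit.terms.index
        assert "diagnosis[colorectal]" in fit.terms.index
        assert "diagnosis[breast]" not in fit.terms.index  # reference level


class TestCorrelations:
    def test_self_and_antithetic(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=500)
        df = pd.DataFrame({"a": x, "b": -x})
        panel = pairwise_correlations(df, variables=["a", "b"])
        assert panel.loc["a", "a"] == pytest.approx(1.0)
        assert panel.loc["a", "b"] == pytest.approx(-1.0)
        assert panel.loc["a", "b"] == panel.loc["b", "a"]

    def test_known_rho_recovered(self):
        rng = np.random.default_rng(20)
        n, rho = 5000, 0.5
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        panel = pairwise_correlations(pd.DataFrame({"x": x, "y": y}),
                                      variables=["x", "y"])
        se = (1 - rho ** 2) / np.sqrt(n)  # Fisher-z scale approximation
        assert abs(panel.loc["x", "y"] - rho) < 3 * se

    def test_zero_variance_not_computable(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        panel = pairwise_correlations(df, variables=["a", "b"])
        assert np.isnan(panel.loc["a", "b"])

    def test_too_few_rows(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ConfigurationError):
            pairwise_correlations(df, variables=["a", "b"])

    def test_panel_on_synthetic_cohort(self, default_cohort):
        """Exertion peaks correlate positively with each other and with
        VO2peak in the generated cohort (the collinearity the screen
        adjusts for)."""
        _, _, cohort = default_cohort
        data = cohort.copy()
        data["plateau_150"] = data["plateau_150"].astype("float")
        panel = pairwise_correlations(data)
        assert panel.loc["rerpeak", "rpepeak"] > 0.2
        assert panel.loc["frpeak", "rerpeak"] > 0.03
        assert (np.diag(panel) == 1.0).all()
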