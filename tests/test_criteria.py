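import numpy as np
import pandas as pd
import pytest

from vo2verify import (CriterionDefinition, combination_counts, default_grid,
                       evaluate_criteria, stratified_vo2_comparison)
from vo2verify.errors import ConfigurationError


def toy_cohort(**overrides):
    base = {
        "rerpeak": [1.16, 0.98, 1.05],
        "rpepeak": [17, 19, 15],
        "pct_predicted_hr": [99.0, 85.0, 91.0],
        "frpeak": [41.0, 39.0, 44.0],
        "plateau_min_delta": [40.0, 120.0, 200.0],
        "vo2peak_rel": [30.0, 25.0, 28.0],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestEvaluateCriteria:
    def test_rer_fulfils_every_cutpoint_below_value(self):
        m = evaluate_criteria(toy_cohort())
        row = m.values.iloc[0]
        for c in ("RER>=1.00", "RER>=1.05", "RER>=1.10", "RER>=1.15"):
            assert row[c]
        assert not m.values.iloc[1]["RER>=1.00"]

    def test_boundary_is_inclusive(self):
        m = evaluate_criteria(toy_cohort())
        assert m.values.iloc[0]["RPE>=17"]          # 17 >= 17
        assert not m.values.iloc[0]["RPE>=18"]
        assert m.values.iloc[0]["plateau<=150"]     # 40 <= 150
        assert not m.values.iloc[2]["plateau<=150"]  # 200

    def test_constructed_full_prevalence(self):
        cohort = toy_cohort(rerpeak=[1.2, 1.01, 1.3])
        m = evaluate_criteria(cohort)
        assert m.percentages["RER>=1.00"] == pytest.approx(100.0)

    def test_missing_cells_excluded_from_margins(self):
        cohort = toy_cohort(rerpeak=[1.2, np.nan, 0.9])
        m = evaluate_criteria(cohort)
        assert m.n_nonmissing["RER>=1.00"] == 2
        assert m.counts["RER>=1.00"] == 1
        assert m.percentages["RER>=1.00"] == pytest.approx(50.0)
        assert pd.isna(m.values.iloc[1]["RER>=1.00"])

    def test_unknown_variable_rejected(self):
        with pytest.raises(ConfigurationError):
            CriterionDefinition("bad", "lactate", ">=", 4.0)
        with pytest.raises(ConfigurationError):
            CriterionDefinition("bad", "rerpeak", "<=", 1.0)

    def test_margins_invariant_to_row_order(self, default_cohort):
        _, _, cohort = default_cohort
        m1 = evaluate_criteria(cohort)
        shuffled = cohort.sample(frac=1.0, random_state=5)
        m2 = evaluate_criteria(shuffled)
        pd.testing.assert_series_equal(m1.percentages, m2.percentages)

    def test_monotone_prevalence_within_variable(self, default_cohort):
        """A stricter cut-point never has higher prevalence."""
        _, _, cohort = default_cohort
        m = evaluate_criteria(cohort)
        pct = m.percentages
        for fam in (["RER>=1.00", "RER>=1.05", "RER>=1.10", "RER>=1.15"],
                    ["RPE>=17", "RPE>=18", "RPE>=19"],
                    ["%predHR>=85", "%predHR>=90", "%predHR>=95"],
                    ["plateau<=150", "plateau<=80", "plateau<=50"]):
            vals = [pct[c] for c in fam]
            assert all(a >= b for a, b in zip(vals, vals[1:])), fam


class TestStratifiedComparison:
    def test_identical_strata_give_p_one(self):
        cohort = toy_cohort(
            rerpeak=[1.2, 1.2, 1.2, 0.9, 0.9, 0.9],
            rpepeak=[17] * 6, pct_predicted_hr=[90.0] * 6, frpeak=[40.0] * 6,
            plateau_min_delta=[100.0] * 6,
            vo2peak_rel=[28.0, 30.0, 32.0, 28.0, 30.0, 32.0])
        m = evaluate_criteria(cohort, [CriterionDefinition("RER>=1.0",
                                                           "rerpeak", ">=", 1.0)])
        out = stratified_vo2_comparison(m, cohort)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "mean_fulfilled"] == out.loc[0, "mean_not_fulfilled"]

    def test_empty_stratum_reported_not_computable(self):
        cohort = toy_cohort(rerpeak=[1.2, 1.3, 1.4])
        m = evaluate_criteria(cohort, [CriterionDefinition("RER>=1.0",
                                                           "rerpeak", ">=", 1.0)])
        out = stratified_vo2_comparison(m, cohort)
        assert not out.loc[0, "computable"]
        assert np.isnan(out.loc[0, "p_value"])

    def test_group_sizes_sum_to_nonmissing(self, default_cohort):
        _, _, cohort = default_cohort
        m = evaluate_criteria(cohort)
        out = stratified_vo2_comparison(m, cohort).set_index("criterion")
        for crit in m.definitions:
            total = (out.loc[crit.name, "n_fulfilled"]
                     + out.loc[crit.name, "n_not_fulfilled"])
            assert total == m.n_nonmissing[crit.name]

    def test_recovers_known_mean_difference(self):
        """Strata drawn as Normal(30, 7) vs Normal(22, 7) with sizes 514/21
        (the kind of split seen for a nearly-universal criterion) recover a
        mean difference of ~8 mL/kg/min."""
        rng = np.random.default_rng(2024)
        diffs, ps = [], []
        for _ in range(40):
            hi = rng.normal(30, 7, 514)
            lo = rng.normal(22, 7, 21)
            cohort = pd.DataFrame({
                "rerpeak": np.r_[np.full(514, 1.2), np.full(21, 0.95)],
                "rpepeak": 17, "pct_predicted_hr": 95.0, "frpeak": 40.0,
                "plateau_min_delta": 100.0,
                "vo2peak_rel": np.r_[hi, lo]})
            m = evaluate_criteria(cohort, [CriterionDefinition(
                "RER>=1.0", "rerpeak", ">=", 1.0)])
            out = stratified_vo2_comparison(m, cohort)
            diffs.append(out.loc[0, "mean_fulfilled"]
                         - out.loc[0, "mean_not_fulfilled"])
            ps.append(out.loc[0, "p_value"])
        se = 7 * np.sqrt(1 / 514 + 1 / 21) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 8.0) < 3 * se
        assert np.median(ps) < 0.001

    def test_welch_p_matches_permutation_oracle(self):
        """On small strata the Welch p-value sits within Monte-Carlo error of
        a 20000-resample permutation test."""
        rng = np.random.default_rng(77)
        a = rng.normal(29, 6, 18)
        b = rng.normal(25, 6, 12)
        cohort = pd.DataFrame({
            "rerpeak": np.r_[np.full(18, 1.2), np.full(12, 0.95)],
            "rpepeak": 17, "pct_predicted_hr": 95.0, "frpeak": 40.0,
            "plateau_min_delta": 100.0, "vo2peak_rel": np.r_[a, b]})
        m = evaluate_criteria(cohort, [CriterionDefinition(
            "RER>=1.0", "rerpeak", ">=", 1.0)])
        welch_p = stratified_vo2_comparison(m, cohort).loc[0, "p_value"]
        pooled = np.r_[a, b]
        obs = abs(a.mean() - b.mean())
        count = 0
        n_res = 20000
        for _ in range(n_res):
            perm = rng.permutation(pooled)
            count += abs(perm[:18].mean() - perm[18:].mean()) >= obs
        perm_p = count / n_res
        mc_se = np.sqrt(perm_p * (1 - perm_p) / n_res)
        assert abs(welch_p - perm_p) < max(5 * mc_se, 0.02)


def test_combination_counts_partition(default_cohort):
    _, _, cohort = default_cohort
    flags = pd.DataFrame({
        "rer": cohort["rerpeak"] >= 1.14,
        "rpe": cohort["rpepeak"] >= 18,
        "fr": cohort["frpeak"] >= 40,
    })
    counts = combination_counts(flags)
    assert counts.sum() == len(cohort)
    assert (counts.index == [0, 1, 2, 3]).all()
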