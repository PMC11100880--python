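"""Synthetic generators: life table, billing, interviews, trial summaries,
and the estimator that turns them back into a parameter table."""

import numpy as np
import pytest

from cohortcea.params import parameter_means
from cohortcea.risk import FEMALE, MALE
from cohortcea.synthetic import (
    DEFAULT_GOMPERTZ,
    GompertzMakeham,
    SyntheticLifeTableSpec,
    estimate_parameters,
    life_expectancy_at,
    make_life_table,
    simulate_billing,
    simulate_interviews,
    simulate_trial_summaries,
    write_synthetic_dataset,
)


class TestMakeLifeTable:
    def test_zero_hazard_gives_zero_qx_except_terminal(self):
        spec = SyntheticLifeTableSpec(params={
            MALE: GompertzMakeham(baseline=0.0, slope=0.1, makeham=0.0)
        })
        lt = make_life_table(spec)
        assert lt.qx(50, MALE) == 0.0
        assert lt.qx(100, MALE) == 1.0

    def test_mortality_rises_with_age(self, life_table):
        for sex in (MALE, FEMALE):
            assert life_table.qx(80, sex) > life_table.qx(50, sex)

    def test_closed_form_at_age_50(self):
        gm = DEFAULT_GOMPERTZ[MALE]
        lt = make_life_table()
        expected = 1 - np.exp(-(gm.makeham + gm.baseline * np.exp(gm.slope * 50)))
        assert lt.qx(50, MALE) == pytest.approx(expected, rel=1e-12)

    def test_deterministic_no_randomness(self):
        a, b = make_life_table(), make_life_table()
        np.testing.assert_array_equal(a.qx_slice(np.arange(0, 101), FEMALE),
                                      b.qx_slice(np.arange(0, 101), FEMALE))

    def test_life_expectancy_in_plausibility_band(self, life_table):
        le = 0.5 * (life_expectancy_at(life_table, 50, MALE)
                    + life_expectancy_at(life_table, 50, FEMALE))
        assert 30.0 <= le <= 33.0


class TestSimulateBilling:
    def test_default_record_counts_match_study(self, rng):
        df, _ = simulate_billing(rng)
        assert (df["setting"] == "outpatient").sum() == 15_533
        assert (df["setting"] == "inpatient").sum() == 2_553

    def test_single_stratum_when_all_weight_on_it(self, rng):
        weights = {("acute_cvd", "central", "inpatient"): 1.0}
        df, _ = simulate_billing(rng, n_outpatient=0, n_inpatient=100,
                                 weights=weights)
        assert len(df) == 100
        assert set(df["level"]) == {"central"}

    def test_stratum_means_recover_truth_within_clt_tolerance(self, rng):
        df, truth = simulate_billing(rng)
        sub = df[(df["service"] == "hypertension") & (df["level"] == "district")]
        x = sub["amount_vnd"]
        tol = 3 * x.std() / np.sqrt(len(x))
        assert abs(x.mean() - truth["c_htn_dist"]) <= tol

    def test_reproducible_under_same_seed(self):
        a, _ = simulate_billing(np.random.default_rng(5), 200, 50)
        b, _ = simulate_billing(np.random.default_rng(5), 200, 50)
        assert a.equals(b)


class TestSimulateInterviews:
    def test_default_size_and_support(self, rng):
        df, _ = simulate_interviews(rng)
        assert len(df) == 178
        assert df["utility"].between(0, 1).all()
        freq_cols = [c for c in df.columns if c.startswith("f_")]
        assert (df[freq_cols] >= 0).all().all()

    def test_female_htn_utility_recovers_truth_at_large_n(self):
        df, truth = simulate_interviews(np.random.default_rng(1), n=20_000)
        sub = df[(df["state"] == "hypertension") & (df["sex"] == FEMALE)]
        x = sub["utility"]
        tol = 3 * x.std() / np.sqrt(len(x))
        assert abs(x.mean() - 0.64) <= tol
        assert truth["u_htn_f"] == 0.64


class TestSimulateTrialSummaries:
    def test_cell_means_recover_published_sbp_at_large_n(self):
        df, _ = simulate_trial_summaries(np.random.default_rng(2), n=40_000)
        target = {("intervention", MALE): 147, ("intervention", FEMALE): 141,
                  ("comparison", MALE): 154, ("comparison", FEMALE): 159}
        for (arm, sex), mean in target.items():
            row = df[(df["arm"] == arm) & (df["sex"] == sex)].iloc[0]
            assert abs(row["sbp_mean"] - mean) <= 3 * row["sbp_se"]

    def test_null_effect_configuration_indistinguishable(self, means):
        truth = dict(means.values)
        for tag in ("m", "f"):
            truth[f"sbp_int_{tag}"] = truth[f"sbp_com_{tag}"]
        df, _ = simulate_trial_summaries(np.random.default_rng(3), n=4_000,
                                         truth=truth)
        m = df.set_index(["arm", "sex"])
        for sex in (MALE, FEMALE):
            gap = (m.loc[("intervention", sex), "sbp_mean"]
                   - m.loc[("comparison", sex), "sbp_mean"])
            se = np.hypot(m.loc[("intervention", sex), "sbp_se"],
                          m.loc[("comparison", sex), "sbp_se"])
            assert abs(gap) <= 3 * se

    def test_comparison_female_smoking_is_structural_zero(self, rng):
        df, _ = simulate_trial_summaries(rng)
        row = df[(df["arm"] == "comparison") & (df["sex"] == FEMALE)].iloc[0]
        assert row["smoke_p"] == 0.0
        assert row["smoke_se"] == 0.0

    def test_too_small_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trial_summaries(rng, n=5)


class TestEstimateParameters:
    def test_billing_recovery_within_three_se(self, rng):
        df, truth = simulate_billing(rng)
        specs = {s.name: s for s in estimate_parameters(billing=df)}
        for name, true_mean in truth.items():
            spec = specs[name]
            assert abs(spec.mean - true_mean) <= 3 * spec.se, name
            assert spec.family == "gamma"

    def test_single_record_stratum_excluded(self, rng):
        df, _ = simulate_billing(rng, n_outpatient=0, n_inpatient=1,
                                 weights={("acute_cvd", "central",
                                           "inpatient"): 1.0})
        assert estimate_parameters(billing=df) == []

    def test_family_assignment_matches_parameter_table(self, specs, rng):
        billing, _ = simulate_billing(rng, 2_000, 500)
        interviews, _ = simulate_interviews(rng, 600)
        # large trial so the rare-smoking cells cannot produce an
        # accidental structural zero
        summaries, _ = simulate_trial_summaries(rng, n=40_000)
        estimated = estimate_parameters(billing, interviews, summaries)
        table_family = {s.name: s.family for s in specs}
        # programme-cost components and CVD mortality rates come from other
        # sources; everything else is estimable from these three datasets
        not_estimable = {"c_int_design", "c_int_implement", "c_int_monitor",
                         "mort_cvd_m", "mort_cvd_f"}
        assert {e.name for e in estimated} == set(table_family) - not_estimable
        for est in estimated:
            assert est.family == table_family[est.name], est.name

    def test_closed_loop_deterministic_result_inside_psa_band(
            self, specs, life_table, risk_eq, config, means):
        """Estimating the parameter table from synthetic data and rerunning
        the analysis lands inside the parameter-uncertainty band of the
        truth (central 95% PSA region)."""
        from cohortcea.analysis import run_deterministic, run_psa

        rng = np.random.default_rng(77)
        billing, _ = simulate_billing(rng)
        interviews, _ = simulate_interviews(rng, n=2_000)
        summaries, _ = simulate_trial_summaries(rng)
        estimated = estimate_parameters(billing, interviews, summaries)
        # mortality rates are not derivable from these sources; keep truth
        values = dict(means.values)
        values.update({s.name: s.mean for s in estimated})
        res = run_deterministic(
            __import__("cohortcea").ParameterSet(values), life_table, risk_eq,
            config,
        )
        psa = run_psa(specs, life_table, risk_eq, config, n_draws=500, seed=4)
        for col, stat in (("dcost", res.delta_cost), ("dqaly", res.delta_qaly)):
            lo, hi = np.quantile(psa[col], [0.025, 0.975])
            assert lo <= stat <= hi, col


def test_write_synthetic_dataset_bundle(tmp_path):
    truth = write_synthetic_dataset(tmp_path, seed=1)
    for fname in ("life_table.csv", "billing.csv", "interviews.csv",
                  "trial_summaries.csv", "parameters.csv", "truth.yaml"):
        assert (tmp_path / fname).exists(), fname
    assert truth["seed"] == 1
    from cohortcea.params import load_parameter_table
    from cohortcea.risk import LifeTable

    lt = LifeTable.from_csv(tmp_path / "life_table.csv")
    assert lt.qx(100, MALE) == 1.0
    specs, report = load_parameter_table(tmp_path / "parameters.csv")
    assert {s.name for s in specs} >= {"c_htn_dist", "u_htn_f", "sbp_com_m"}
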