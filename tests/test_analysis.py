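"""ICER verdicts, deterministic layer, tornado, PSA, CEAC and CE plane."""

import math

import numpy as np
import pandas as pd
import pytest

from cohortcea.analysis import (
    Verdict,
    ce_plane_summary,
    ceac,
    default_wtp_grid,
    icer,
    one_way_sensitivity,
    run_deterministic,
    run_psa,
)
from cohortcea.markov import COMPARISON, INTERVENTION
from cohortcea.params import ParameterSet, ParameterSpec, parameter_means


class TestIcer:
    def test_simple_ratio(self):
        res = icer(2_000_000, 0.5)
        assert res.verdict == Verdict.RATIO
        assert res.value == pytest.approx(4_000_000)

    def test_dominant(self):
        assert icer(-1, 0.1).verdict == Verdict.DOMINANT

    def test_dominated(self):
        assert icer(1, -0.1).verdict == Verdict.DOMINATED

    def test_southwest_flagged_ratio(self):
        res = icer(-100, -0.1)
        assert res.verdict == Verdict.SOUTHWEST
        assert res.value == pytest.approx(1000)

    def test_zero_effect_never_divides(self):
        assert icer(5, 0).verdict == Verdict.UNDEFINED
        assert icer(5, 0).value is None

    @pytest.mark.parametrize("dc", [-1.0, 0.0, 1.0])
    @pytest.mark.parametrize("de", [-1.0, 0.0, 1.0])
    def test_verdict_table_is_total(self, dc, de):
        res = icer(dc, de)
        assert isinstance(res.verdict, Verdict)


class TestRunDeterministic:
    def test_identical_arms_undefined_verdict(self, means, life_table,
                                              risk_eq, config):
        values = dict(means.values)
        for tag in ("m", "f"):
            values[f"sbp_int_{tag}"] = values[f"sbp_com_{tag}"]
            values[f"smoke_int_{tag}"] = values[f"smoke_com_{tag}"]
        for c in ("c_int_design", "c_int_implement", "c_int_monitor"):
            values[c] = 0.0
        res = run_deterministic(ParameterSet(values), life_table, risk_eq,
                                config)
        assert res.delta_cost == 0.0
        assert res.delta_ly == 0.0
        assert res.delta_qaly == 0.0
        assert res.icer_per_qaly.verdict == Verdict.UNDEFINED

    def test_incomplete_set_lists_missing_names(self, life_table, risk_eq,
                                                config, means):
        values = dict(means.values)
        values.pop("u_htn_m")
        with pytest.raises(ValueError, match="u_htn_m"):
            run_deterministic(ParameterSet(values), life_table, risk_eq,
                              config)

    def test_regression_snapshot_on_synthetic_standins(self, means, life_table,
                                                       risk_eq, config):
        """Frozen first-build snapshot under the packaged synthetic
        life table and risk equation (NOT the published study numbers)."""
        res = run_deterministic(means, life_table, risk_eq, config)
        assert res.comparison.cost_disc == pytest.approx(163_793_055.3, abs=1.0)
        assert res.intervention.cost_disc == pytest.approx(160_490_101.5, abs=1.0)
        assert res.delta_qaly == pytest.approx(0.0538964, abs=1e-6)
        assert res.delta_ly == pytest.approx(0.0176379, abs=1e-6)
        assert res.comparison.ly == pytest.approx(31.0814, abs=1e-3)


@pytest.fixture(scope="module")
def entries(specs, life_table, risk_eq, config):
    return one_way_sensitivity(specs, life_table, risk_eq, config)


class TestOneWaySensitivity:
    def test_sorted_by_descending_width(self, entries):
        widths = [e.width for e in entries if not math.isnan(e.width)]
        assert widths == sorted(widths, reverse=True)

    def test_zero_se_parameter_has_zero_width(self, entries):
        by_name = {e.name: e for e in entries}
        e = by_name["mort_cvd_f"]  # printed SE 0.000 -> point mass
        assert e.low == e.high
        assert e.width == 0.0

    def test_fixed_parameters_excluded(self, entries):
        assert "smoke_com_f" not in {e.name for e in entries}

    def test_pure_cost_parameter_leaves_qaly_untouched(self, specs, life_table,
                                                       risk_eq, config, means):
        spec = next(s for s in specs if s.name == "c_travel_outpt")
        from cohortcea.params import ci95

        dqalys = []
        for bound in ci95(spec):
            values = dict(means.values)
            values["c_travel_outpt"] = bound
            res = run_deterministic(ParameterSet(values), life_table, risk_eq,
                                    config)
            dqalys.append(res.delta_qaly)
        assert dqalys[0] == dqalys[1]

    def test_influential_parameter_ranked_before_inert(self, specs, life_table,
                                                       risk_eq, config):
        pair = [s for s in specs if s.name in ("f_inpt_cent", "c_meals_outpt")]
        sub = one_way_sensitivity(
            pair + [s for s in specs if s not in pair], life_table, risk_eq,
            config
        )
        names = [e.name for e in sub]
        assert names.index("f_inpt_cent") < names.index("c_meals_outpt")

    def test_order_invariant_to_spec_list_order(self, specs, life_table,
                                                risk_eq, config, entries):
        reordered = one_way_sensitivity(list(reversed(specs)), life_table,
                                        risk_eq, config)
        assert [e.name for e in reordered] == [e.name for e in entries]


class TestRunPsa:
    def test_single_draw_reproducible(self, specs, life_table, risk_eq,
                                      config):
        a = run_psa(specs, life_table, risk_eq, config, n_draws=1, seed=99)
        b = run_psa(specs, life_table, risk_eq, config, n_draws=1, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_draw_prefix_stable_under_larger_n(self, specs, life_table,
                                               risk_eq, config):
        # draw i depends only on (seed, i), not on n_draws
        small = run_psa(specs, life_table, risk_eq, config, n_draws=2, seed=5)
        large = run_psa(specs, life_table, risk_eq, config, n_draws=4, seed=5)
        pd.testing.assert_frame_equal(small, large.iloc[:2])

    def test_all_fixed_specs_reproduce_deterministic(self, specs, life_table,
                                                     risk_eq, config, means):
        fixed = [ParameterSpec(s.name, "fixed", s.mean) for s in specs]
        psa = run_psa(fixed, life_table, risk_eq, config, n_draws=3, seed=1)
        det = run_deterministic(means, life_table, risk_eq, config)
        assert np.allclose(psa["dcost"], det.delta_cost)
        assert np.allclose(psa["dqaly"], det.delta_qaly)
        assert np.allclose(psa["dly"], det.delta_ly)

    def test_mean_consistency_between_seeds(self, specs, life_table, risk_eq,
                                            config):
        big = run_psa(specs, life_table, risk_eq, config, n_draws=600, seed=10)
        half = run_psa(specs, life_table, risk_eq, config, n_draws=300, seed=11)
        se = np.sqrt(big["dqaly"].var() / 600 + half["dqaly"].var() / 300)
        assert abs(big["dqaly"].mean() - half["dqaly"].mean()) <= 3 * se


def synthetic_cloud(n=10_000, seed=0, mean_dc=1.9e6, mean_dq=0.05):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "draw": np.arange(n),
        "dcost": rng.normal(mean_dc, 2e6, n),
        "dqaly": rng.normal(mean_dq, 0.03, n),
        "dly": rng.normal(0.02, 0.01, n),
    })


class TestCeac:
    def test_dominant_draws_always_cost_effective(self):
        draws = pd.DataFrame({"dcost": [-1.0, -2.0], "dqaly": [0.1, 0.2]})
        curve = ceac(draws, np.array([0.0, 1e6, 1e8]))
        assert np.all(curve.probability == 1.0)

    def test_zero_wtp_limit_is_probability_of_saving(self):
        draws = synthetic_cloud()
        curve = ceac(draws, np.array([0.0]))
        assert curve.probability[0] == (draws["dcost"] < 0).mean()

    def test_two_draw_hand_enumeration(self):
        draws = pd.DataFrame({"dcost": [1.0, 3.0], "dqaly": [1.0, 1.0]})
        curve = ceac(draws, np.array([2.0]))
        assert curve.probability[0] == 0.5  # 2*1-1>0 yes; 2*1-3>0 no

    def test_tie_counts_as_not_cost_effective(self):
        draws = pd.DataFrame({"dcost": [2.0], "dqaly": [1.0]})
        assert ceac(draws, np.array([2.0])).probability[0] == 0.0

    def test_monotone_nondecreasing_for_nonnegative_gains(self):
        # per-draw NMB is nondecreasing in the threshold iff dqaly >= 0
        draws = synthetic_cloud()
        draws["dqaly"] = draws["dqaly"].abs()
        curve = ceac(draws, default_wtp_grid())
        assert np.all(np.diff(curve.probability) >= 0)

    def test_large_wtp_limit_is_probability_of_gaining(self):
        draws = synthetic_cloud()
        curve = ceac(draws, np.array([1e15]))
        assert curve.probability[0] == pytest.approx(
            (draws["dqaly"] > 0).mean(), abs=1e-3
        )

    def test_grid_contains_gdp_anchors(self):
        grid = default_wtp_grid()
        assert 86_400_000.0 in grid
        assert 259_200_000.0 in grid
        assert np.all(np.diff(grid) > 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(synthetic_cloud(100), np.array([]))


class TestCePlane:
    def test_single_draw_in_ne(self):
        draws = pd.DataFrame({"dcost": [1.0], "dqaly": [1.0]})
        s = ce_plane_summary(draws)
        assert s.ne == 1.0 and s.nw == s.se == s.sw == 0.0

    def test_symmetric_cloud_quarters(self):
        rng = np.random.default_rng(8)
        draws = pd.DataFrame({"dcost": rng.normal(0, 1, 40_000),
                              "dqaly": rng.normal(0, 1, 40_000)})
        s = ce_plane_summary(draws)
        for frac in (s.ne, s.nw, s.se, s.sw):
            assert frac == pytest.approx(0.25, abs=3 * 0.5 / 200)

    def test_fractions_sum_to_one_with_boundary_draws(self):
        draws = pd.DataFrame({"dcost": [0.0, 1.0, -1.0, 0.0],
                              "dqaly": [0.0, -1.0, 0.0, 2.0]})
        s = ce_plane_summary(draws)
        assert s.ne + s.nw + s.se + s.sw == pytest.approx(1.0)
        assert s.ne == 0.5  # both boundary draws count to the positive side
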