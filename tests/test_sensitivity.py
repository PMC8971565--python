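"""Tornado, PSA, and subgroup analyses."""

import numpy as np
import pandas as pd
import pytest

from stroke_cea import ParameterSet, null_scenario, one_way, run_psa, subgroups, tornado
from stroke_cea.sensitivity import DEFAULT_CEAC_GRID


class TestOneWay:
    def test_degenerate_sweep_reproduces_base_case(self, params, life_table, base_eval):
        base = params["ticagrelor_additional"]
        entry = one_way("ticagrelor_additional", base, base, params, life_table)
        assert entry.icer_at_low == entry.icer_at_high
        assert entry.icer_at_low == pytest.approx(base_eval[2].icer, rel=1e-12)
        assert entry.span == 0.0

    def test_endpoints_bracket_base_case_for_drug_cost(self, params, life_table, base_eval):
        entry = one_way("ticagrelor_additional", 174, 593, params, life_table)
        assert entry.icer_at_low < base_eval[2].icer < entry.icer_at_high

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            one_way("no_such_parameter", 0, 1)

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            one_way("ticagrelor_additional", 593, 174)


@pytest.fixture(scope="module")
def frame(params, life_table):
    return tornado(params, life_table)


class TestTornado:
    def test_sorted_by_span_descending(self, frame):
        spans = frame["span"].to_numpy()
        assert np.all(np.diff(spans[~np.isnan(spans)]) <= 0)

    def test_mrs_proportions_and_settings_excluded(self, frame):
        names = set(frame["parameter"])
        assert not any(n.endswith("_mrs3") and "utility" not in n
                       and "mortality" not in n for n in names)
        assert "wtp" not in names and "discount_annual" not in names

    def test_mortality_hrs_swept_at_1p96_sd(self, frame):
        row = frame.set_index("parameter").loc["mortality_hr_mrs5"]
        assert row["low"] == pytest.approx(2.37 - 1.96 * 0.237)
        assert row["high"] == pytest.approx(2.37 + 1.96 * 0.237)

    def test_probability_endpoints_truncated(self, frame):
        probs = frame.set_index("parameter").loc["aspirin_p_major_ech"]
        assert probs["low"] >= 0.0

    def test_drug_cost_and_hr_among_top_drivers(self, frame):
        top = set(frame.head(4)["parameter"])
        assert "ticagrelor_additional" in top or "hr_primary" in top


class TestPSA:
    def test_same_seed_reproduces_samples_exactly(self, params, life_table):
        a = run_psa(200, seed=7, params=params, life_table=life_table)
        b = run_psa(200, seed=7, params=params, life_table=life_table)
        pd.testing.assert_frame_equal(a.samples, b.samples, check_exact=True)
        assert a.frac_cost_effective == b.frac_cost_effective

    def test_different_seeds_differ(self, params, life_table):
        a = run_psa(50, seed=1, params=params, life_table=life_table)
        b = run_psa(50, seed=2, params=params, life_table=life_table)
        assert not a.samples["delta_qaly"].equals(b.samples["delta_qaly"])

    def test_point_mass_distributions_reproduce_base_case(self, params, life_table,
                                                          base_eval):
        from stroke_cea.parameters import DistributionSpec, registry
        dists = {n: DistributionSpec("point", params[n])
                 for n, d in registry().items() if d.dist is not None}
        frozen = params.with_overrides({}, dist_overrides=dists)
        res = run_psa(5, seed=3, params=frozen, life_table=life_table)
        np.testing.assert_allclose(res.samples["delta_qaly"],
                                   base_eval[2].delta_qaly, rtol=1e-12)
        assert res.frac_cost_effective in (0.0, 1.0)

    def test_ceac_monotone_grid_and_fraction_bounds(self, params, life_table):
        res = run_psa(300, seed=11, params=params, life_table=life_table)
        assert res.ceac["wtp"].tolist() == DEFAULT_CEAC_GRID.tolist()
        assert res.ceac["fraction"].between(0, 1).all()
        assert 0.0 <= res.frac_cost_effective <= 1.0

    def test_sampled_parameters_cover_all_distributed_inputs(self, params, life_table):
        from stroke_cea.parameters import registry
        res = run_psa(10, seed=5, params=params, life_table=life_table)
        sampled = {n for n, d in registry().items() if d.sampled}
        assert sampled == set(res.samples.columns) - {
            "iteration", "delta_cost", "delta_qaly", "cost_effective"}


class TestSubgroups:
    def test_base_row_consistent_with_one_way(self, params, life_table, base_eval):
        table = pd.DataFrame([{"label": "Overall", "hr_mean": 0.83,
                               "hr_low": 0.71, "hr_high": 0.96}])
        [row] = subgroups(table, params, life_table)
        entry = one_way("hr_primary", 0.71, 0.96, params, life_table)
        assert row.icer_mean == pytest.approx(base_eval[2].icer, rel=1e-12)
        assert row.icer_low == pytest.approx(entry.icer_at_low, rel=1e-12)
        assert row.icer_high == pytest.approx(entry.icer_at_high, rel=1e-12)

    def test_empty_table_gives_empty_result(self, params, life_table):
        assert subgroups(pd.DataFrame(), params, life_table) == []

    def test_nonpositive_hr_rejected(self, params, life_table):
        table = pd.DataFrame([{"label": "bad", "hr_mean": -1.0,
                               "hr_low": 0.5, "hr_high": 1.5}])
        with pytest.raises(ValueError):
            subgroups(table, params, life_table)


class TestNullScenarioSensitivity:
    def test_psa_on_null_scenario_is_always_equivalent(self):
        scn = null_scenario()
        res = run_psa(50, seed=13, params=scn.params, life_table=scn.life_table)
        np.testing.assert_array_equal(res.samples["delta_cost"], 0.0)
        np.testing.assert_array_equal(res.samples["delta_qaly"], 0.0)

    def test_tornado_on_null_scenario_spans_zero_except_arm_asymmetric(self):
        scn = null_scenario()
        frame = tornado(scn.params, scn.life_table)
        asym = frame["parameter"].str.startswith(("ticagrelor", "aspirin", "hr_"))
        symmetric = frame.loc[~asym, "span"]
        # shared-parameter sweeps move both arms together: span exactly 0
        # (ICER undefined at delta-QALY 0 -> NaN spans count as no asymmetry)
        assert ((symmetric == 0) | symmetric.isna()).all()
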