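"""Markov engine: transitions, reallocation, accrual, and oracles."""

import numpy as np
import pytest

from stroke_cea import (
    CohortState,
    ParameterSet,
    constant_hazard_scenario,
    default_life_table,
    monthly_recurrence_probability,
    reallocation_weights,
    run_cohort,
    step,
)
from stroke_cea.decision_tree import acute_phase
from stroke_cea.markov import run_cohort_arrays, engine_inputs
from stroke_cea.mortality import LifeTable


class TestRecurrenceProbability:
    def test_worked_example_first_year(self):
        assert monthly_recurrence_probability(0.122, 1.03, 0.0) == \
            pytest.approx(0.010784, abs=1e-6)

    def test_zero_rate(self):
        assert monthly_recurrence_probability(0.0, 1.03, 5.0) == 0.0

    def test_escalation_is_exactly_rr_on_hazard_scale(self):
        p0 = monthly_recurrence_probability(0.122, 1.03, 0.0)
        p1 = monthly_recurrence_probability(0.122, 1.03, 1.0)
        h0, h1 = -np.log1p(-p0), -np.log1p(-p1)
        assert h1 / h0 == pytest.approx(1.03, rel=1e-12)

    def test_escalation_steps_at_whole_years(self):
        early = monthly_recurrence_probability(0.122, 1.03, 0.2)
        late = monthly_recurrence_probability(0.122, 1.03, 0.9)
        assert early == late


class TestReallocation:
    def test_uniform_over_equal_or_greater_disability(self):
        assert reallocation_weights(2) == {2: 0.25, 3: 0.25, 4: 0.25, 5: 0.25}

    def test_most_disabled_state_keeps_all_mass(self):
        assert reallocation_weights(5) == {5: 1.0}

    def test_least_disabled_state_spreads_over_all(self):
        w = reallocation_weights(0)
        assert w == {s: pytest.approx(1 / 6) for s in range(6)}

    @pytest.mark.parametrize("s", range(6))
    def test_weights_sum_to_one(self, s):
        assert sum(reallocation_weights(s).values()) == pytest.approx(1.0)


def _constant_table(monthly_death):
    qx = 1.0 - (1.0 - monthly_death) ** 12
    return LifeTable(np.arange(65, 111), np.full(46, qx), stroke_fraction=0.0)


class TestStep:
    def test_all_dead_cohort_is_absorbing(self, params, life_table):
        state = CohortState(np.array([0, 0, 0, 0, 0, 0, 1.0]), cycle=5,
                            age=65 + 4 / 12)
        nxt, inc = step(state, params, life_table)
        np.testing.assert_array_equal(nxt.occupancy, state.occupancy)
        assert inc["cost"] == 0.0 and inc["qaly"] == 0.0

    def test_geometric_decay_without_recurrence(self):
        """With one alive state, no recurrence, constant monthly death d,
        death occupancy after k steps is 1 - (1-d)^k."""
        scn = constant_hazard_scenario(0.01, utility=1.0, discount=0.0)
        state = CohortState(np.array([1.0, 0, 0, 0, 0, 0, 0]), cycle=1, age=65.0)
        for k in range(1, 25):
            state, _ = step(state, scn.params, scn.life_table)
            assert state.occupancy[6] == pytest.approx(1 - 0.99**k, abs=1e-12)

    def test_mass_conserved_with_recurrence(self, params, life_table):
        occ = np.array([0.3, 0.3, 0.1, 0.1, 0.1, 0.05, 0.05])
        state = CohortState(occ, cycle=10, age=65 + 9 / 12)
        for _ in range(24):
            state, _ = step(state, params, life_table)
            assert state.occupancy.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(state.occupancy >= 0)


class TestRunCohort:
    def _arm_result(self, scenario):
        ps = scenario.params
        acute = acute_phase(ps.acute("aspirin"), ps.costs(), ps.utilities(), 0.0)
        return run_cohort(acute, ps, scenario.life_table)

    def test_closed_form_geometric_qaly(self):
        scn = constant_hazard_scenario(0.01, utility=1.0, discount=0.0)
        res = self._arm_result(scn)
        assert res.total_qaly == pytest.approx(scn.expected["total_qaly"], abs=1e-9)
        assert scn.expected["total_qaly"] == pytest.approx(8.110, abs=1e-3)
        assert res.total_cost == 0.0

    @pytest.mark.parametrize("d,u,r", [(0.0, 1.0, 0.0), (0.005, 0.7, 0.03),
                                       (0.02, 0.3, 0.05)])
    def test_oracle_equivalence_across_configurations(self, d, u, r):
        scn = constant_hazard_scenario(d, utility=u, discount=r)
        res = self._arm_result(scn)
        assert res.total_qaly == pytest.approx(scn.expected["total_qaly"], abs=1e-9)

    def test_no_death_no_discount_gives_full_horizon(self):
        scn = constant_hazard_scenario(0.0, utility=1.0, discount=0.0)
        assert self._arm_result(scn).total_qaly == pytest.approx(30.0, abs=1e-9)

    def test_zero_utilities_give_zero_qaly(self, life_table):
        ps = ParameterSet().with_overrides({
            **{f"utility_mrs{s}": 0.0 for s in range(6)},
            "disutility_recurrent_stroke": 0.0, "disutility_major_ech": 0.0,
        })
        acute = acute_phase(ps.acute("aspirin"), ps.costs(), ps.utilities(), 0.0)
        assert run_cohort(acute, ps, life_table).total_qaly == 0.0

    def test_occupancy_conserved_and_death_monotone(self, base_eval):
        trace = base_eval[0].trace.frame
        occ = trace[[f"mrs{s}" for s in range(6)] + ["death"]].to_numpy()
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace["death"].to_numpy()) >= 0)

    def test_discounting_only_shrinks_totals(self, params, life_table):
        from stroke_cea.pipeline import evaluate
        undiscounted = params.with_overrides({"discount_annual": 0.0})
        a0, _, _ = evaluate(undiscounted, life_table)
        a3, _, _ = evaluate(params, life_table)
        assert a0.total_qaly > a3.total_qaly
        assert a0.total_cost > a3.total_cost

    def test_monotone_in_utilities_and_tariffs(self, params, life_table, base_eval):
        from stroke_cea.pipeline import evaluate
        richer = params.with_overrides({"utility_mrs3": 0.60})
        ra, _, _ = evaluate(richer, life_table)
        assert ra.total_qaly > base_eval[0].total_qaly
        pricier = params.with_overrides({"annual_post_dependent": 20000})
        pa, _, _ = evaluate(pricier, life_table)
        assert pa.total_cost > base_eval[0].total_cost

    def test_trace_csv_round_trip(self, base_eval, tmp_path):
        from stroke_cea.markov import CohortTrace
        path = tmp_path / "trace.csv"
        base_eval[0].trace.to_csv(path)
        back = CohortTrace.read_csv(path)
        assert len(back.frame) == 360
        np.testing.assert_allclose(back.frame["qaly_inc_disc"].sum(),
                                   base_eval[0].total_qaly, rtol=1e-9)

    def test_life_table_too_short_rejected(self, params):
        short = LifeTable(np.arange(65, 80), np.full(15, 0.01))
        ps = params
        acute = acute_phase(ps.acute("aspirin"), ps.costs(), ps.utilities(), 0.0)
        with pytest.raises(ValueError, match="life table"):
            run_cohort(acute, ps, short)


class TestBatchScalarConsistency:
    def test_batched_engine_matches_scalar_run(self, params, life_table, base_eval):
        ps = params
        acute = acute_phase(ps.acute("aspirin"), ps.costs(), ps.utilities(), 0.0)
        ep = engine_inputs(ps.to_dict())
        out = run_cohort_arrays(np.tile(acute.start_vector, (3, 1)),
                                np.full(3, acute.acute_cost),
                                np.full(3, acute.acute_qaly),
                                ep, life_table, ps.econ())
        np.testing.assert_array_equal(out["total_qaly"],
                                      np.full(3, base_eval[0].total_qaly))
        np.testing.assert_array_equal(out["total_cost"],
                                      np.full(3, base_eval[0].total_cost))
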