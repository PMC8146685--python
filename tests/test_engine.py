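"""Markov cohort engine: competing risks, traces, rewards, microsimulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gepnet_cea.engine import (StateSpec, accumulate_rewards, build_model,
                               combine_competing_risks, discount_factor,
                               microsim_oracle, run_cohort)
from gepnet_cea.lifetable import annual_to_cycle_prob, life_expectancy
from gepnet_cea.strategies import background_mortality
from gepnet_cea.parameters import ParameterSet


def two_state_decay(p=0.5, n_cycles=60, utility=1.0, cost=0.0):
    """Alive -> Dead at constant per-cycle probability."""
    return build_model(
        [StateSpec("Alive", cost_per_cycle=cost, utility=utility,
                   exits={"Dead": p}),
         StateSpec("Dead")],
        initial_state="Alive", absorbing=["Dead"], n_cycles=n_cycles)


class TestCompetingRisks:
    def test_single_event_passes_through(self):
        assert combine_competing_risks({"A": 0.1}) == {"A": pytest.approx(0.1)}

    def test_symmetric_pair_shares_total_exit(self):
        out = combine_competing_risks({"A": 0.2, "B": 0.2})
        # total exit 1 - 0.8*0.8 = 0.36, split equally
        assert out["A"] == pytest.approx(0.18)
        assert out["B"] == pytest.approx(0.18)

    def test_null_event_unaffected(self):
        out = combine_competing_risks({"A": 0.0, "B": 0.3})
        assert out["A"] == 0.0
        assert out["B"] == pytest.approx(0.3)

    def test_empty_map(self):
        assert combine_competing_risks({}) == {}

    def test_certain_event_alone_is_allowed(self):
        assert combine_competing_risks({"A": 1.0, "B": 0.0}) == {"A": 1.0, "B": 0.0}

    def test_two_certain_or_competing_certain_events_rejected(self):
        with pytest.raises(ValueError):
            combine_competing_risks({"A": 1.0, "B": 0.2})
        with pytest.raises(ValueError):
            combine_competing_risks({"A": 1.0, "B": 1.0})

    def test_matches_exponential_time_microsimulation(self):
        # independent exponential event times, keep events landing within
        # one cycle: empirical shares must match the apportionment rule
        pa, pb = 0.2, 0.35
        out = combine_competing_risks({"A": pa, "B": pb})
        rng = np.random.default_rng(7)
        n = 400_000
        ta = rng.exponential(1.0 / -math.log1p(-pa), n)
        tb = rng.exponential(1.0 / -math.log1p(-pb), n)
        t = np.minimum(ta, tb)
        a_first = (ta < tb) & (t < 1.0)
        b_first = (tb <= ta) & (t < 1.0)
        for key, emp in (("A", a_first.mean()), ("B", b_first.mean())):
            se = math.sqrt(out[key] * (1 - out[key]) / n)
            assert emp == pytest.approx(out[key], abs=4 * se)

    @given(st.lists(st.floats(min_value=0.0, max_value=0.99), min_size=1,
                    max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_probabilities_sum_below_one(self, probs):
        out = combine_competing_risks({f"e{i}": p for i, p in enumerate(probs)})
        total = sum(out.values())
        assert total <= 1.0 + 1e-12
        # total exit equals the joint-survival complement
        expect = 1.0 - math.prod(1.0 - p for p in probs)
        assert total == pytest.approx(expect, abs=1e-12)


class TestCohortTrace:
    def test_absorbing_start_is_stationary(self):
        m = build_model([StateSpec("Alive", exits={"Dead": 0.1}),
                         StateSpec("Dead")],
                        initial_state="Dead", absorbing=["Dead"], n_cycles=10)
        trace = run_cohort(m)
        assert np.all(trace.occupancy == trace.occupancy[0])

    def test_geometric_decay(self):
        trace = run_cohort(two_state_decay(p=0.5, n_cycles=20))
        np.testing.assert_allclose(trace.column("Alive"), 0.5 ** np.arange(21))

    def test_rows_conserve_mass(self, base_params, life_table):
        from gepnet_cea.strategies import build_strategy
        for label in ("SSA", "DELAY"):
            trace = run_cohort(build_strategy(base_params, label, life_table))
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                       atol=1e-10)

    def test_absorbing_occupancy_nondecreasing(self, base_params, life_table):
        from gepnet_cea.strategies import build_strategy
        trace = run_cohort(build_strategy(base_params, "SSA", life_table))
        for dead in ("DeadNET", "DeadOther"):
            assert np.all(np.diff(trace.column(dead)) >= -1e-12)

    def test_certain_exit_probability_rejected_in_model_assembly(self):
        # competing-risk combination bounds adjusted rows by 1, so the
        # only way to break row-stochasticity is a marginal p >= 1
        with pytest.raises(ValueError):
            build_model([StateSpec("A", exits={"B": 1.0, "C": 0.5}),
                         StateSpec("B"), StateSpec("C")],
                        initial_state="A", absorbing=["B", "C"], n_cycles=2)


class TestDiscounting:
    @pytest.mark.parametrize("t,rate,expected", [
        (0, 0.03, 1.0),
        (12, 0.03, 1.0 / 1.03),
        (7, 0.0, 1.0),
    ])
    def test_known_factors(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestRewards:
    def test_full_health_year(self):
        m = build_model([StateSpec("Alive", utility=1.0, exits={"Dead": 0.0}),
                         StateSpec("Dead")],
                        initial_state="Alive", absorbing=["Dead"], n_cycles=12)
        totals = accumulate_rewards(run_cohort(m), m, annual_rate=0.0)
        assert totals.total_qaly == pytest.approx(1.0)
        assert totals.total_ly == pytest.approx(1.0)

    def test_dead_cohort_accrues_nothing(self):
        m = build_model([StateSpec("Alive", utility=1.0, exits={"Dead": 0.2}),
                         StateSpec("Dead")],
                        initial_state="Dead", absorbing=["Dead"], n_cycles=24)
        totals = accumulate_rewards(run_cohort(m), m, annual_rate=0.03)
        assert totals.total_cost == totals.total_qaly == totals.total_ly == 0.0

    def test_geometric_life_years_closed_form(self):
        # LY = (1/12) * sum_t 0.5*(0.5^t + 0.5^(t+1)) = (1/12) * 1.5 = 0.125
        m = two_state_decay(p=0.5, n_cycles=60)
        totals = accumulate_rewards(run_cohort(m), m, annual_rate=0.0)
        assert totals.total_ly == pytest.approx(0.125, abs=1e-9)

    def test_qaly_never_exceeds_ly(self, base_params, life_table):
        from gepnet_cea.strategies import build_strategy
        m = build_strategy(base_params, "SSA", life_table)
        totals = accumulate_rewards(run_cohort(m), m, base_params.discount_annual)
        assert totals.total_qaly <= totals.total_ly

    def test_totals_nonincreasing_in_discount_rate(self):
        m = two_state_decay(p=0.05, n_cycles=120, utility=0.8, cost=100.0)
        trace = run_cohort(m)
        prev = None
        for rate in (0.0, 0.01, 0.03, 0.06):
            tot = accumulate_rewards(trace, m, rate)
            if prev is not None:
                assert tot.total_cost <= prev.total_cost
                assert tot.total_qaly <= prev.total_qaly
            prev = tot


class TestMicrosimOracle:
    def test_absorbing_start_yields_exact_zero(self):
        m = build_model([StateSpec("Alive", utility=1.0, exits={"Dead": 0.3}),
                         StateSpec("Dead")],
                        initial_state="Dead", absorbing=["Dead"], n_cycles=12)
        totals, se = microsim_oracle(m, 500, seed=1, annual_rate=0.03)
        assert totals.total_ly == 0.0 and totals.total_qaly == 0.0

    def test_same_seed_reproduces(self):
        m = two_state_decay(p=0.3, n_cycles=24, utility=0.7, cost=10.0)
        a, _ = microsim_oracle(m, 2000, seed=42, annual_rate=0.03)
        b, _ = microsim_oracle(m, 2000, seed=42, annual_rate=0.03)
        assert a == b

    def test_agrees_with_cohort_expectation(self):
        m = two_state_decay(p=0.1, n_cycles=120, utility=0.8, cost=250.0)
        exact = accumulate_rewards(run_cohort(m), m, annual_rate=0.03)
        est, se = microsim_oracle(m, 100_000, seed=11, annual_rate=0.03)
        for field in ("total_cost", "total_qaly", "total_ly"):
            assert abs(getattr(est, field) - getattr(exact, field)) \
                <= 3 * se[field]


def test_background_only_model_matches_life_table_expectancy(life_table):
    """No-disease limit: the monthly cohort model must reproduce the
    annual life-table expectancy at age 60 to within discretization."""
    params = ParameterSet()
    p_bg = background_mortality(params, life_table)
    m = build_model([StateSpec("Alive", utility=1.0, exits={"Dead": p_bg}),
                     StateSpec("Dead")],
                    initial_state="Alive", absorbing=["Dead"],
                    n_cycles=params.n_cycles)
    totals = accumulate_rewards(run_cohort(m), m, annual_rate=0.0)
    assert totals.total_ly == pytest.approx(life_expectancy(life_table, 60),
                                            abs=0.02)
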