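"""Transition-matrix construction, cohort iteration and cost/QALY accrual."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from ptsdcea import (
    CohortTrace,
    MortalityTable,
    RegressionMap,
    Scenario,
    StateCostTable,
    TherapyProfile,
    accrue,
    band_crossing_prob,
    build_transition_matrix,
    discount_factor,
    per_cycle_prob,
    run_cohort,
    run_strategy,
)
from ptsdcea.engine import build_state_space
from ptsdcea.scenario import DEFAULT_BANDS


def make_scenario(**overrides) -> Scenario:
    """Minimal two-strategy scenario with every stochastic event switched off."""
    strategy = dict(
        per_session_cost=0.0, sessions_per_course=0.0, per_course_cost=0.0,
        annual_drug_cost=0.0, dropout_course_prob=0.0, relapse_prob=0.0,
        retreatment_prob=0.0, effect_mean=0.0, effect_dispersion=0.0,
    )
    base = dict(
        name="toy",
        strategies=[
            TherapyProfile(name="a", **strategy),
            TherapyProfile(name="b", **strategy),
        ],
        state_costs=StateCostTable(quarterly_cost_by_band={
            "severe": 0.0, "moderate": 0.0, "mild": 0.0, "asymptomatic": 0.0,
        }),
        mortality=MortalityTable(quarterly_death_prob_by_band={
            "severe": 0.0, "moderate": 0.0, "mild": 0.0, "asymptomatic": 0.0,
        }),
        initial_distribution={"severe": 0.4, "moderate": 0.3, "mild": 0.3},
        annual_discount_rate=0.0,
    )
    base.update(overrides)
    return Scenario.model_validate(base)


class TestPerCycleProb:
    def test_zero_and_identity(self):
        assert per_cycle_prob(0.0, 7) == 0.0
        assert per_cycle_prob(0.42, 1) == pytest.approx(0.42)

    def test_closed_form_and_inverse(self):
        p = per_cycle_prob(0.33, 2)
        assert p == pytest.approx(1 - 0.67**0.5, abs=1e-12)
        assert 1 - (1 - p) ** 2 == pytest.approx(0.33, abs=1e-12)

    def test_degenerate_probability_rejected(self):
        with pytest.raises(ValueError):
            per_cycle_prob(1.0, 4)


class TestBandCrossingProb:
    def test_no_improvement_cannot_cross(self):
        assert band_crossing_prob(DEFAULT_BANDS[1], (0.0, 0.0)) == 0.0

    def test_reduction_exceeding_band_width_always_crosses(self):
        # moderate band [40, 59]: a certain 30-point drop clears any in-band score
        assert band_crossing_prob(DEFAULT_BANDS[1], (30.0, 0.0)) == 1.0

    def test_monotone_in_effect_mean(self):
        band = DEFAULT_BANDS[0]
        probs = [band_crossing_prob(band, (m, 2.5)) for m in np.linspace(0, 25, 26)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    @pytest.mark.parametrize("mean,sd", [(7.01, 2.883), (2.0, 5.0), (15.0, 1.0)])
    def test_matches_quadrature(self, mean, sd):
        for band in DEFAULT_BANDS[:3]:
            w = band.width
            oracle = quad(lambda d: norm.sf(d, loc=mean, scale=sd), 0, w)[0] / w
            assert band_crossing_prob(band, (mean, sd)) == pytest.approx(
                oracle, abs=1e-9
            )


class TestTransitionMatrix:
    def test_all_zero_events_give_identity(self):
        tm = build_transition_matrix(make_scenario(), make_scenario().strategies[0])
        assert np.allclose(tm.probs, np.eye(len(tm.states)))

    def test_near_certain_dropout_moves_mass_to_dropped_out(self):
        scn = make_scenario()
        strategy = scn.strategies[0].model_copy(
            update={"dropout_course_prob": 1 - 1e-12}
        )
        tm = build_transition_matrix(scn, strategy)
        for i, s in enumerate(tm.states):
            if s.kind == "on_treatment":
                j = next(
                    k for k, t in enumerate(tm.states)
                    if t.kind == "dropped_out" and t.band == s.band
                )
                assert tm.probs[i, j] == pytest.approx(1.0, abs=1e-9)

    def test_fixture_rows_sum_to_one(self, all_fixtures):
        for scn in all_fixtures:
            for strategy in scn.strategies:
                tm = build_transition_matrix(scn, strategy)
                assert np.abs(tm.probs.sum(axis=1) - 1).max() < 1e-12
                assert tm.probs.min() >= 0

    def test_dead_row_absorbing_and_asymptomatic_exits_only_to_dead(self, nf_psych):
        tm = build_transition_matrix(nf_psych, nf_psych.strategies[0])
        i_dead = next(i for i, s in enumerate(tm.states) if s.kind == "dead")
        i_asym = next(i for i, s in enumerate(tm.states) if s.kind == "asymptomatic")
        assert tm.probs[i_dead, i_dead] == 1.0
        off = [j for j in range(len(tm.states)) if j not in (i_asym, i_dead)]
        assert np.all(tm.probs[i_asym, off] == 0)


class TestRunCohort:
    def test_identity_matrix_constant_trace(self):
        trace = run_cohort(make_scenario(), make_scenario().strategies[0])
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_pure_death_closed_form(self):
        # all bands die with p = 0.5/cycle: alive share is 0.5^t
        scn = make_scenario(mortality=MortalityTable(quarterly_death_prob_by_band={
            "severe": 0.5, "moderate": 0.5, "mild": 0.5, "asymptomatic": 0.5,
        }))
        trace = run_cohort(scn, scn.strategies[0])
        i_dead = next(i for i, s in enumerate(trace.states) if s.kind == "dead")
        alive = 1 - trace.occupancy[:, i_dead]
        assert np.allclose(alive, 0.5 ** np.arange(13), atol=1e-12)

    def test_conservation_and_dead_monotone(self, all_fixtures):
        for scn in all_fixtures:
            for strategy in scn.strategies:
                trace = run_cohort(scn, strategy)
                assert np.abs(trace.occupancy.sum(axis=1) - 1).max() < 1e-9
                i_dead = next(
                    i for i, s in enumerate(trace.states) if s.kind == "dead"
                )
                dead = trace.occupancy[:, i_dead]
                assert np.all(np.diff(dead) >= -1e-15)


class TestDiscounting:
    def test_reference_factors(self):
        assert discount_factor(0.03, 0, 0.25) == 1.0
        assert discount_factor(0.03, 4, 0.25) == pytest.approx(1 / 1.03)
        assert discount_factor(0.0, 9, 0.25) == 1.0

    def test_zero_rate_discounted_equals_undiscounted(self, nf_psych):
        scn = nf_psych.model_copy(update={"annual_discount_rate": 0.0})
        _, res = run_strategy(scn, 0)
        assert np.array_equal(res.cost, res.cost_disc)
        assert np.array_equal(res.qaly, res.qaly_disc)

    def test_discounted_never_exceeds_undiscounted(self, nf_psych):
        _, res = run_strategy(nf_psych, 0)
        assert np.all(res.cost_disc <= res.cost + 1e-12)
        assert np.all(res.qaly_disc <= res.qaly + 1e-12)


class TestAccrue:
    def test_all_dead_trace_accrues_nothing(self, nf_psych):
        states = build_state_space(nf_psych)
        occ = np.zeros((nf_psych.horizon_cycles + 1, len(states)))
        occ[:, [i for i, s in enumerate(states) if s.kind == "dead"][0]] = 1.0
        res = accrue(CohortTrace(states=states, occupancy=occ),
                     nf_psych, nf_psych.strategies[0])
        assert res.total_cost == 0.0
        assert res.total_qaly == 0.0

    def test_cohort_fixed_in_mild_costs_printed_care_rate(self):
        # one cycle in mild with no therapy -> USD 3450 of quarterly care
        scn = make_scenario(
            state_costs=StateCostTable(quarterly_cost_by_band={
                "severe": 5880.0, "moderate": 4900.0,
                "mild": 3450.0, "asymptomatic": 0.0,
            }),
            initial_distribution={"mild": 1.0},
            horizon_cycles=1,
        )
        _, res = run_strategy(scn, 0)
        assert res.cost[0] == pytest.approx(3450.0)

    def test_full_health_qaly_annuity(self):
        # utility ~ 1 cohort: discounted QALY is the closed-form annuity sum
        scn = make_scenario(
            initial_distribution={"asymptomatic": 1.0},
            annual_discount_rate=0.03,
            regression=RegressionMap(intercept=200.0, slope=-1e-9),
        )
        _, res = run_strategy(scn, 0)
        expected = sum(0.25 * 1.03 ** (-0.25 * t) for t in range(12))
        assert res.total_qaly == pytest.approx(expected, rel=1e-9)

    def test_cumulative_by_year_partitions_totals(self, nf_psych):
        _, res = run_strategy(nf_psych, 0)
        by_year = res.cumulative_by_year()
        assert list(by_year) == [1, 2, 3]
        assert by_year[3][0] == pytest.approx(res.total_cost, rel=1e-12)
        assert by_year[3][1] == pytest.approx(res.total_qaly, rel=1e-12)
        costs = [by_year[y][0] for y in (1, 2, 3)]
        assert costs == sorted(costs)

    def test_half_cycle_correction_reduces_cost_of_shrinking_cohort(self, nf_psych):
        _, plain = run_strategy(nf_psych, 0)
        _, half = run_strategy(nf_psych.model_copy(update={"half_cycle": True}), 0)
        # occupancy of costly symptomatic states declines, so midpoint valuation
        # yields a strictly lower total cost
        assert half.total_cost < plain.total_cost
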