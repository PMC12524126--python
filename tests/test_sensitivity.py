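"""PSA, one-way sweeps, threshold solving and tornado ordering."""

import numpy as np
import pytest

from ptsdcea import (
    DistributionSpec,
    MortalityTable,
    Scenario,
    StateCostTable,
    TherapyProfile,
    find_threshold,
    one_way,
    run_psa,
    tornado,
)
from ptsdcea.sensitivity import (
    default_tornado_ranges,
    get_param,
    valid_paths,
    with_param,
)


def linear_cost_scenario() -> Scenario:
    """No events, no discounting: delta cost is linear in any cost parameter."""
    strategy = dict(
        per_session_cost=0.0, sessions_per_course=0.0,
        annual_drug_cost=0.0, dropout_course_prob=0.0, relapse_prob=0.0,
        retreatment_prob=0.0, effect_mean=0.0, effect_dispersion=0.0,
    )
    return Scenario.model_validate(dict(
        name="linear",
        strategies=[
            TherapyProfile(name="a", per_course_cost=100.0, **strategy),
            TherapyProfile(name="b", per_course_cost=50.0, **strategy),
        ],
        state_costs=StateCostTable(quarterly_cost_by_band={
            "severe": 0.0, "moderate": 0.0, "mild": 0.0, "asymptomatic": 0.0,
        }),
        mortality=MortalityTable(quarterly_death_prob_by_band={
            "severe": 0.0, "moderate": 0.0, "mild": 0.0, "asymptomatic": 0.0,
        }),
        initial_distribution={"moderate": 1.0},
        annual_discount_rate=0.0,
    ))


class TestParameterPaths:
    def test_get_and_set_round_trip(self, nf_psych):
        path = "strategies.psychotherapy.dropout_course_prob"
        assert get_param(nf_psych, path) == pytest.approx(0.206)
        updated = with_param(nf_psych, path, 0.1)
        assert get_param(updated, path) == 0.1
        assert get_param(nf_psych, path) == pytest.approx(0.206)  # original intact

    def test_unknown_path_lists_valid_ones(self, nf_psych):
        with pytest.raises(KeyError, match="valid paths"):
            with_param(nf_psych, "strategies.psychotherapy.nope", 1.0)

    def test_every_advertised_path_resolves(self, nf_psych):
        for path in valid_paths(nf_psych):
            get_param(nf_psych, path)

    def test_psa_paths_exist_in_all_fixtures(self, all_fixtures):
        for scn in all_fixtures:
            for path in scn.psa_distributions:
                get_param(scn, path)


class TestPSA:
    def test_seed_reproducible(self, nf_psych):
        a = run_psa(nf_psych, n=100, seed=11)
        b = run_psa(nf_psych, n=100, seed=11)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)

    def test_different_seeds_differ(self, nf_psych):
        a = run_psa(nf_psych, n=50, seed=1)
        b = run_psa(nf_psych, n=50, seed=2)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_degenerate_all_fixed_distributions(self, nf_psych):
        scn = nf_psych.model_copy(deep=True)
        scn.psa_distributions = {
            path: DistributionSpec(family="fixed", param_a=get_param(scn, path))
            for path in list(scn.psa_distributions)[:4]
        }
        res = run_psa(scn, n=20, seed=3)
        assert np.all(res.delta_cost == res.delta_cost[0])
        for frac in (res.fraction_dominant, res.fraction_cheaper,
                     res.fraction_dominated):
            assert frac in (0.0, 1.0)

    def test_forced_dominance(self):
        # intervention is cheaper and more effective with certainty
        scn = linear_cost_scenario()
        strategies = scn.model_dump()["strategies"]
        strategies[0].update(per_course_cost=10.0, effect_mean=10.0)
        strategies[1].update(per_course_cost=500.0, dropout_course_prob=0.5)
        scn = scn.model_copy(update={
            "strategies": [TherapyProfile(**s) for s in strategies],
            "psa_distributions": {
                "state_costs.moderate": DistributionSpec(
                    family="gamma", derived_from=[1000.0, 100.0]
                ),
            },
        })
        res = run_psa(scn, n=50, seed=4)
        assert res.fraction_dominant == 1.0

    def test_quadrant_fractions_sum_to_one(self, nf_psych):
        res = run_psa(nf_psych, n=300, seed=5)
        assert sum(res.quadrant_fractions().values()) == pytest.approx(1.0)
        assert res.fraction_dominant <= res.fraction_cheaper

    def test_ceac_boundary_identities(self, nf_psych):
        res = run_psa(nf_psych, n=300, seed=6)
        assert res.ceac_at(0.0) == np.mean(res.delta_cost < 0)
        assert res.ceac_at(1e13) == np.mean(res.delta_qaly > 0)

    def test_missing_distributions_rejected(self, nf_psych):
        scn = nf_psych.model_copy(update={"psa_distributions": {}})
        with pytest.raises(ValueError, match="psa_distributions"):
            run_psa(scn, n=10, seed=0)


class TestOneWay:
    def test_inert_parameter_gives_flat_curve(self, nf_psych):
        curve = one_way(nf_psych, "wtp_per_qaly", 0.0, 100_000.0, n_points=4)
        assert curve.delta_cost.nunique() == 1
        assert curve.delta_qaly.nunique() == 1

    def test_sweeping_intervention_dropout_degrades_its_qalys(self, nf_psych):
        curve = one_way(nf_psych, "strategies.nf_ot.dropout_course_prob",
                        0.05, 0.6, n_points=7)
        deltas = curve.delta_qaly.to_numpy()
        assert np.all(np.diff(deltas) <= 1e-12)

    def test_two_points_are_the_endpoints(self, nf_psych):
        curve = one_way(nf_psych, "strategies.nf_ot.effect_mean", 2.0, 9.0,
                        n_points=2)
        assert list(curve.value) == [2.0, 9.0]

    def test_inverted_interval_rejected(self, nf_psych):
        with pytest.raises(ValueError, match="low"):
            one_way(nf_psych, "strategies.nf_ot.effect_mean", 9.0, 2.0)


class TestFindThreshold:
    def test_linear_toy_closed_form(self):
        # delta cost = 12 * (p - 50): root at the comparator's course cost
        scn = linear_cost_scenario()
        th = find_threshold(scn, "strategies.a.per_course_cost", 1.0, 400.0,
                            tol=1e-6)
        assert th.threshold_value == pytest.approx(50.0, abs=1e-6)
        # beyond the root, a's course cost exceeds b's, so b becomes cheaper
        assert th.direction == "b"

    def test_sign_flips_across_threshold(self, nf_psych):
        param = "strategies.psychotherapy.dropout_course_prob"
        th = find_threshold(nf_psych, param, 0.01, 0.5)
        eps = 1e-3
        lo = one_way(nf_psych, param, th.threshold_value - eps,
                     th.threshold_value + eps, n_points=2)
        assert np.sign(lo.delta_cost.iloc[0]) != np.sign(lo.delta_cost.iloc[1])

    def test_matches_grid_scan(self, nf_psych):
        param = "strategies.psychotherapy.dropout_course_prob"
        th = find_threshold(nf_psych, param, 0.01, 0.5)
        grid = one_way(nf_psych, param, 0.01, 0.5, n_points=1001)
        signs = np.sign(grid.delta_cost.to_numpy())
        flip = np.nonzero(np.diff(signs))[0][0]
        step = grid.value.iloc[1] - grid.value.iloc[0]
        assert abs(th.threshold_value - grid.value.iloc[flip]) <= step

    def test_no_sign_change_is_an_error(self, nf_psych):
        with pytest.raises(ValueError, match="no threshold in range"):
            find_threshold(nf_psych, "strategies.nf_ot.effect_mean", 5.0, 9.0)


class TestTornado:
    def test_single_parameter_single_bar(self, nf_psych):
        res = tornado(nf_psych, {"strategies.nf_ot.effect_mean": (5.0, 9.0)})
        assert len(res.entries) == 1

    def test_zero_influence_parameter_sorts_last_with_zero_width(self, nf_psych):
        res = tornado(nf_psych, {
            "strategies.nf_ot.dropout_course_prob": (0.05, 0.4),
            "wtp_per_qaly": (0.0, 100_000.0),
        })
        last = res.entries[-1]
        assert last[0] == "wtp_per_qaly"
        assert last[3] == last[4]

    def test_entries_sorted_by_descending_width(self, nf_psych):
        res = tornado(nf_psych, default_tornado_ranges(nf_psych))
        widths = [abs(hi - lo) for _, _, _, lo, hi in res.entries]
        assert widths == sorted(widths, reverse=True)

    def test_dropout_outranks_retreatment_on_base_case(self, nf_psych):
        res = tornado(nf_psych, default_tornado_ranges(nf_psych))
        order = [e[0] for e in res.entries]
        for s in ("nf_ot", "psychotherapy"):
            assert order.index(f"strategies.{s}.dropout_course_prob") < order.index(
                f"strategies.{s}.retreatment_prob"
            )

    def test_empty_ranges_rejected(self, nf_psych):
        with pytest.raises(ValueError, match="non-empty"):
            tornado(nf_psych, {})
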