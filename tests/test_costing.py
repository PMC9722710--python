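"""Costing: mistimed-birth adjustment, totals, incremental comparisons."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocddi import (
    BirthAdjustmentParams,
    CohortDDIModel,
    EventCounts,
    adjust_birth_cost,
    compare_strategies,
    evaluate_strategy,
    evaluate_strategy_bundle,
    total_costs,
)
from ocddi import published

ADJ = BirthAdjustmentParams(f=0.6, disc_rate=0.03, d=2)


class TestAdjustBirthCost:
    def test_no_mistimed_births_leaves_cost_unchanged(self):
        adj = BirthAdjustmentParams(f=0.0, disc_rate=0.03, d=2)
        assert adjust_birth_cost(12953, adj) == 12953

    def test_maximum_birth_cost_matches_published_adjusted_maximum(self):
        # 28,664 x (1 - 0.6/1.03^2) = 12,452.86, printed as 12,453
        assert adjust_birth_cost(28664, ADJ) == pytest.approx(12452.8585164, rel=1e-9)

    def test_median_birth_cost_adjusts_by_formula(self):
        # formula value; deliberately differs from the published adjusted
        # median summary (5,497), which summarizes differently-derived costs
        assert adjust_birth_cost(12953, ADJ) == pytest.approx(5627.33311339, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_birth_cost(0, ADJ)
        with pytest.raises(ValueError):
            adjust_birth_cost(100, BirthAdjustmentParams(f=1.2, disc_rate=0.03, d=2))

    @given(
        cost=st.floats(1, 1e6),
        f=st.floats(0.01, 0.99),
        r=st.floats(0, 0.2),
        d=st.floats(0, 10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_cost_strictly_between_zero_and_unadjusted(self, cost, f, r, d):
        adjusted = adjust_birth_cost(cost, BirthAdjustmentParams(f=f, disc_rate=r, d=d))
        assert 0 < adjusted < cost


class TestTotalCosts:
    def test_zero_events_give_zero_totals(self, basecase):
        events = EventCounts({o: 0.0 for o in basecase.costs})
        totals = total_costs(events, basecase.costs, "unadjusted")
        assert totals.total == (0.0, 0.0, 0.0)

    def test_strategy2_birth_total_matches_published_cell(self, fitted):
        r = fitted.strategy("OC + enzyme inducer")
        med, lo, hi = r.costs_unadjusted.by_outcome["birth"]
        assert med == pytest.approx(144903, rel=1e-3)
        assert lo == pytest.approx(58955, rel=1e-3)
        assert hi == pytest.approx(320660, rel=1e-3)

    def test_ectopic_cost_nonzero_despite_zero_displayed_count(self, fitted):
        r = fitted.strategy("OC + enzyme inducer")
        assert r.events.displayed_by_outcome["ectopic_pregnancy"] == 0
        assert r.costs_unadjusted.by_outcome["ectopic_pregnancy"][0] == pytest.approx(
            702, rel=1e-3
        )

    def test_unknown_outcome_key_is_configuration_error(self, basecase):
        events = EventCounts({"birth": 1.0, "twin_birth": 1.0})
        with pytest.raises(KeyError):
            total_costs(events, basecase.costs, "unadjusted")

    def test_unknown_mode_rejected(self, basecase):
        events = EventCounts({o: 1.0 for o in basecase.costs})
        with pytest.raises(ValueError):
            total_costs(events, basecase.costs, "discounted")

    def test_adjusted_total_below_unadjusted(self, fitted):
        for r in fitted.columns:
            for a, u in zip(r.costs_adjusted.total, r.costs_unadjusted.total):
                assert a < u  # all strategies have a birth component

    def test_linearity_in_unit_costs_and_cohort_size(self, basecase):
        spec = basecase.strategy("OC + enzyme inducer")
        base = evaluate_strategy(spec, "point", basecase)
        doubled_costs = {k: c.scaled(2.0) for k, c in basecase.costs.items()}
        cfg2 = dataclasses.replace(basecase, costs=doubled_costs)
        twice = evaluate_strategy(spec, "point", cfg2)
        assert twice.costs_unadjusted.total == pytest.approx(
            tuple(2 * x for x in base.costs_unadjusted.total), rel=1e-12
        )
        cfg3 = dataclasses.replace(
            basecase, settings=dataclasses.replace(basecase.settings, cohort_size=2000)
        )
        big = evaluate_strategy(spec, "point", cfg3)
        assert big.events.total_up == pytest.approx(2 * base.events.total_up, rel=1e-12)
        assert big.costs_adjusted.total == pytest.approx(
            tuple(2 * x for x in base.costs_adjusted.total), rel=1e-12
        )


class TestEvaluateStrategy:
    def test_lower_ci_variant_displays_nineteen_pregnancies(self, fitted):
        assert fitted.strategy("OC + enzyme inducer", "low").events.displayed_total_up == 19

    def test_strategy1_unadjusted_total_matches_published(self, fitted):
        assert fitted.strategy("OC alone").costs_unadjusted.total_median == pytest.approx(
            20682, rel=1e-3
        )

    def test_zero_rate_strategy_gives_zero_events_and_costs(self, basecase):
        import ocddi

        spec = ocddi.StrategySpec(name="none", rate_point=0.0)
        r = evaluate_strategy(spec, "point", basecase)
        assert r.events.total_up == 0.0
        assert r.costs_unadjusted.total == (0.0, 0.0, 0.0)

    def test_missing_ci_variant_is_configuration_error(self, basecase):
        spec = basecase.strategy("OC alone")  # no CI bounds
        with pytest.raises(Exception, match="CI bound"):
            evaluate_strategy(spec, "low", basecase)

    @pytest.mark.parametrize(
        "key, col",
        [(col, j) for j, col in enumerate(published.COLUMNS)],
        ids=[f"{s}-{v}" for s, v in published.COLUMNS],
    )
    def test_every_published_cost_cell_reproduces(self, fitted, key, col):
        strategy, variant = key
        r = fitted.strategy(strategy, variant)
        computed = {
            "birth_unadjusted": r.costs_unadjusted.by_outcome["birth"],
            "birth_adjusted": r.costs_adjusted.by_outcome["birth"],
            "induced_abortion_unadjusted": r.costs_unadjusted.by_outcome["induced_abortion"],
            "spontaneous_abortion_unadjusted": r.costs_unadjusted.by_outcome["spontaneous_abortion"],
            "ectopic_pregnancy_unadjusted": r.costs_unadjusted.by_outcome["ectopic_pregnancy"],
            "total_unadjusted": r.costs_unadjusted.total,
            "total_adjusted": r.costs_adjusted.total,
        }
        for row_name, triple in computed.items():
            # published cells are rounded to the nearest dollar, hence abs=0.5
            want = published.COSTS[row_name][col]
            assert triple == pytest.approx(want, rel=1e-3, abs=0.5), row_name


class TestCompareStrategies:
    def test_strategy_vs_itself_is_all_zero(self, basecase):
        b = evaluate_strategy_bundle(basecase.strategy("OC + enzyme inducer"), basecase)
        inc = compare_strategies(b, b)
        assert inc.delta_up == 0
        assert inc.delta_cost_unadjusted == (0.0, 0.0, 0.0)
        assert inc.delta_cost_adjusted == (0.0, 0.0, 0.0)

    def test_swapping_comparator_and_reference_negates_everything(self, basecase):
        a = evaluate_strategy_bundle(basecase.strategy("OC + enzyme inducer"), basecase)
        b = evaluate_strategy_bundle(basecase.strategy("OC + enzyme neutral"), basecase)
        fwd, rev = compare_strategies(a, b), compare_strategies(b, a)
        assert fwd.delta_up == -rev.delta_up
        for m in ("unadjusted", "adjusted"):
            assert fwd.delta_cost(m) == pytest.approx(
                tuple(-x for x in rev.delta_cost(m)), abs=1e-9
            )

    def test_adjusted_median_delta_matches_headline_figure(self, fitted):
        inc = fitted.incremental("OC + enzyme inducer", "OC alone")
        assert inc.delta_cost_adjusted[0] == pytest.approx(65146, rel=1e-3)

    def test_inducer_vs_neutral_unadjusted_range(self, fitted):
        inc = fitted.incremental("OC + enzyme inducer", "OC + enzyme neutral")
        assert inc.delta_cost_unadjusted[1] == pytest.approx(14309, rel=1e-3)
        assert inc.delta_cost_unadjusted[2] == pytest.approx(158452, rel=1e-3)
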