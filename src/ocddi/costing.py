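"""Cost aggregation and incremental comparison.

Expected event counts are multiplied, unrounded, by per-outcome unit-cost
summaries (median, min, max propagated independently as a deterministic
interval — min with min, max with max).  Two costing modes exist:

* ``unadjusted`` — unit costs straight from the cost table;
* ``adjusted`` — the birth unit costs are first passed through the
  mistimed-birth adjustment ``cost * (1 - f / (1 + r)^d)``.

Within-horizon discounting is deliberately absent; the discount rate enters
only through the mistimed-birth adjustment.

Incremental comparisons subtract corresponding summary bounds between two
strategies: medians at point-estimate rates, the minimum total at each
strategy's lowest available rate variant, and the maximum total at its
highest available variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .config import (
    OUTCOME_STATES,
    BirthAdjustmentParams,
    CostSummary,
    ModelConfig,
    StrategySpec,
)
from .engine import (
    EventCounts,
    build_transition_matrix,
    expected_events,
    rate_to_prob,
    round_display,
    run_cohort_trace,
)

__all__ = [
    "CostTotals",
    "StrategyResult",
    "StrategyBundle",
    "IncrementalResult",
    "adjust_birth_cost",
    "total_costs",
    "evaluate_strategy",
    "evaluate_strategy_bundle",
    "compare_strategies",
]


def adjust_birth_cost(cost: float, adj: BirthAdjustmentParams) -> float:
    """Apply the mistimed-birth adjustment to a per-birth unit cost.

    Returns ``cost * (1 - f * (1 + disc_rate) ** -d)``: the fraction ``f``
    of births that is merely mistimed contributes only the difference between
    paying now and paying ``d`` years later at discount rate ``disc_rate``.
    """
    if not cost > 0:
        raise ValueError(f"cost must be > 0, got {cost}")
    bad = adj.violations()
    if bad:
        raise ValueError("invalid adjustment params: " + "; ".join(map(str, bad)))
    return cost * (1.0 - adj.f * (1.0 + adj.disc_rate) ** (-adj.d))


@dataclass(frozen=True)
class CostTotals:
    """Per-outcome and grand cost totals, each as (median, min, max) USD."""

    by_outcome: dict[str, tuple[float, float, float]]
    adjusted: bool

    @property
    def total(self) -> tuple[float, float, float]:
        return tuple(
            math.fsum(self.by_outcome[o][i] for o in self.by_outcome) for i in range(3)
        )

    @property
    def total_median(self) -> float:
        return self.total[0]

    @property
    def total_min(self) -> float:
        return self.total[1]

    @property
    def total_max(self) -> float:
        return self.total[2]


def total_costs(
    events: EventCounts,
    costs: Mapping[str, CostSummary],
    mode: str,
    adj: BirthAdjustmentParams | None = None,
) -> CostTotals:
    """Multiply unrounded expected counts by unit costs, per summary bound.

    ``mode`` is ``"unadjusted"`` or ``"adjusted"``; in adjusted mode each of
    the birth unit-cost bounds is transformed by :func:`adjust_birth_cost`
    before multiplication, so the adjustment propagates to median, min and
    max alike.
    """
    if mode not in ("adjusted", "unadjusted"):
        raise ValueError(f"mode must be 'adjusted' or 'unadjusted', got {mode!r}")
    unknown = set(events.by_outcome) - set(costs)
    if unknown:
        raise KeyError(f"no unit costs for outcome(s) {sorted(unknown)}")
    by_outcome: dict[str, tuple[float, float, float]] = {}
    for outcome in OUTCOME_STATES:
        unit = costs[outcome]
        if mode == "adjusted" and outcome == "birth":
            if adj is None:
                raise ValueError("adjusted mode requires adjustment parameters")
            unit = CostSummary(
                median=adjust_birth_cost(unit.median, adj),
                min=adjust_birth_cost(unit.min, adj),
                max=adjust_birth_cost(unit.max, adj),
            )
        n = events.by_outcome[outcome]
        by_outcome[outcome] = (n * unit.median, n * unit.min, n * unit.max)
    return CostTotals(by_outcome=by_outcome, adjusted=(mode == "adjusted"))


@dataclass(frozen=True)
class StrategyResult:
    """One strategy evaluated at one rate variant: counts plus both costings."""

    strategy: str
    variant: str  # point | low | high
    rate: float
    events: EventCounts
    costs_unadjusted: CostTotals
    costs_adjusted: CostTotals

    def costs(self, mode: str) -> CostTotals:
        if mode == "unadjusted":
            return self.costs_unadjusted
        if mode == "adjusted":
            return self.costs_adjusted
        raise ValueError(f"unknown costing mode {mode!r}")


def evaluate_strategy(
    spec: StrategySpec, variant: str, cfg: ModelConfig
) -> StrategyResult:
    """Run the full pipeline for one strategy at one rate variant.

    Composes rate-to-probability conversion, transition-matrix assembly, the
    cohort trace, event extraction and both costing modes.
    """
    rate = spec.rate(variant)
    p_fail = rate_to_prob(rate, cfg.settings.cycle_length)
    matrix = build_transition_matrix(p_fail, cfg.outcomes)
    trace = run_cohort_trace(matrix, cfg.settings)
    events = expected_events(trace)
    return StrategyResult(
        strategy=spec.name,
        variant=variant,
        rate=rate,
        events=events,
        costs_unadjusted=total_costs(events, cfg.costs, "unadjusted"),
        costs_adjusted=total_costs(events, cfg.costs, "adjusted", cfg.adjustment),
    )


@dataclass(frozen=True)
class StrategyBundle:
    """All available rate variants of one strategy under one config."""

    strategy: str
    results: dict[str, StrategyResult]  # keyed by variant

    @property
    def point(self) -> StrategyResult:
        return self.results["point"]

    @property
    def lowest(self) -> StrategyResult:
        """Result at the lowest available rate (lower CI bound if present)."""
        return self.results.get("low", self.results["point"])

    @property
    def highest(self) -> StrategyResult:
        return self.results.get("high", self.results["point"])


def evaluate_strategy_bundle(spec: StrategySpec, cfg: ModelConfig) -> StrategyBundle:
    return StrategyBundle(
        strategy=spec.name,
        results={v: evaluate_strategy(spec, v, cfg) for v in spec.variants},
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental burden of a comparator strategy over a reference.

    ``delta_up`` is the difference of the displayed (integer) unintended
    pregnancy counts at point-estimate rates.  Cost deltas subtract bound
    for bound: median totals at point rates; minimum totals at each
    strategy's lowest variant; maximum totals at its highest variant.
    """

    comparator: str
    reference: str
    delta_up: int
    delta_cost_unadjusted: tuple[float, float, float]  # (median, min, max)
    delta_cost_adjusted: tuple[float, float, float]

    def delta_cost(self, mode: str) -> tuple[float, float, float]:
        if mode == "unadjusted":
            return self.delta_cost_unadjusted
        if mode == "adjusted":
            return self.delta_cost_adjusted
        raise ValueError(f"unknown costing mode {mode!r}")


def compare_strategies(a: StrategyBundle, b: StrategyBundle) -> IncrementalResult:
    """Incremental events and costs of strategy ``a`` over strategy ``b``."""

    def delta(mode: str) -> tuple[float, float, float]:
        return (
            a.point.costs(mode).total_median - b.point.costs(mode).total_median,
            a.lowest.costs(mode).total_min - b.lowest.costs(mode).total_min,
            a.highest.costs(mode).total_max - b.highest.costs(mode).total_max,
        )

    return IncrementalResult(
        comparator=a.strategy,
        reference=b.strategy,
        delta_up=a.point.events.displayed_total_up - b.point.events.displayed_total_up,
        delta_cost_unadjusted=delta("unadjusted"),
        delta_cost_adjusted=delta("adjusted"),
    )
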