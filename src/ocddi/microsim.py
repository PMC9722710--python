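"""Individual-level microsimulation: synthetic cohorts and a stochastic oracle.

Each woman is simulated independently, month by month: she fails her
contraceptive in a given cycle with the same per-cycle probability the
cohort engine uses, so her time to failure is geometric; on failure an
outcome is drawn from the unintended-pregnancy outcome distribution and a
unit cost is attached.  Aggregated over many women this converges to the
deterministic cohort trace, which makes the simulator an independent
check on the engine (and a generator of realistic individual-level data
for testing every downstream stage).

Randomness comes from a counter-based Philox bit generator keyed by the
seed; all per-woman draws are made as whole arrays (one uniform for the
failure time via the inverse geometric CDF, one for the outcome), so the
result is reproducible and independent of any iteration order.

Cost sampling is a point mass at the median unit cost by default, matching
the deterministic engine's median pathway; a triangular(min, median, max)
mode is available as an exploratory extension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OUTCOME_STATES, ModelConfig, StrategySpec
from .costing import CostTotals
from .engine import EventCounts, rate_to_prob

__all__ = ["SimWoman", "SimResult", "simulate_cohort", "convergence_report"]


@dataclass(frozen=True)
class SimWoman:
    """One simulated woman: failure cycle (1-based), outcome and cost draw.

    All three are ``None`` together when her contraception held for the
    whole horizon.
    """

    id: int
    failure_cycle: int | None
    outcome: str | None
    cost_draw: float | None


@dataclass(frozen=True)
class SimResult:
    """Aggregate of one simulated cohort plus the full individual roster.

    The roster is stored as parallel arrays (``_cycles`` uses -1 for "never
    failed") and materialized as :class:`SimWoman` records on demand.
    """

    counts: dict[str, int]
    total_up: int
    total_cost: float
    seed: int
    n_women: int
    _cycles: np.ndarray
    _outcome_idx: np.ndarray
    _cost: np.ndarray

    @property
    def roster(self) -> tuple[SimWoman, ...]:
        failed = self._cycles >= 0
        return tuple(
            SimWoman(
                id=i,
                failure_cycle=int(self._cycles[i]) if failed[i] else None,
                outcome=OUTCOME_STATES[self._outcome_idx[i]] if failed[i] else None,
                cost_draw=float(self._cost[i]) if failed[i] else None,
            )
            for i in range(self.n_women)
        )

    def roster_frame(self) -> pd.DataFrame:
        failed = self._cycles >= 0
        outcomes = np.array(OUTCOME_STATES, dtype=object)[self._outcome_idx]
        return pd.DataFrame(
            {
                "id": np.arange(self.n_women),
                "failure_cycle": np.where(failed, self._cycles, pd.NA),
                "outcome": np.where(failed, outcomes, pd.NA),
                "cost_draw": np.where(failed, self._cost, np.nan),
            }
        )

    def roster_to_csv(self, path) -> None:
        self.roster_frame().to_csv(path, index=False)

    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_women": self.n_women,
                "seed": self.seed,
                "total_unintended_pregnancies": self.total_up,
                "counts": self.counts,
                "total_cost": self.total_cost,
            },
            indent=2,
        )


def simulate_cohort(
    cfg: ModelConfig,
    strategy: StrategySpec,
    variant: str = "point",
    n_women: int = 1000,
    seed: int = 0,
    cost_sampling: str = "median",
) -> SimResult:
    """Simulate ``n_women`` independent women over the model horizon.

    Parameters
    ----------
    cost_sampling : "median" or "triangular"
        "median" assigns every event its median unit cost (the deterministic
        engine's median pathway); "triangular" draws from a
        triangular(min, median, max) distribution per event.
    """
    if n_women < 1:
        raise ValueError(f"n_women must be >= 1, got {n_women}")
    if cost_sampling not in ("median", "triangular"):
        raise ValueError(f"unknown cost_sampling mode {cost_sampling!r}")
    rate = strategy.rate(variant)
    p = rate_to_prob(rate, cfg.settings.cycle_length)
    n_cycles = cfg.settings.n_cycles
    rng = np.random.Generator(np.random.Philox(key=seed))

    # Inverse-geometric failure times: cycle = ceil(log(1-u)/log(1-p)).
    u_fail = rng.random(n_women)
    if p >= 1.0:
        cycle = np.ones(n_women, dtype=np.int64)
    elif p <= 0.0:
        cycle = np.full(n_women, n_cycles + 1, dtype=np.int64)
    else:
        cycle = np.ceil(np.log1p(-u_fail) / math.log1p(-p)).astype(np.int64)
        np.maximum(cycle, 1, out=cycle)
    failed = cycle <= n_cycles

    # Outcome draw for every woman (used only where failed) keeps the draw
    # count fixed, so adding cycles never reshuffles downstream streams.
    u_out = rng.random(n_women)
    cum = np.cumsum([cfg.outcomes[o] for o in OUTCOME_STATES])
    outcome_idx = np.searchsorted(cum, u_out, side="right")
    np.minimum(outcome_idx, len(OUTCOME_STATES) - 1, out=outcome_idx)

    medians = np.array([cfg.costs[o].median for o in OUTCOME_STATES])
    if cost_sampling == "median":
        cost = medians[outcome_idx]
    else:
        lo = np.array([cfg.costs[o].min for o in OUTCOME_STATES])[outcome_idx]
        md = medians[outcome_idx]
        hi = np.array([cfg.costs[o].max for o in OUTCOME_STATES])[outcome_idx]
        cost = rng.triangular(lo, md, hi)

    counts = {
        o: int(np.count_nonzero(failed & (outcome_idx == k)))
        for k, o in enumerate(OUTCOME_STATES)
    }
    return SimResult(
        counts=counts,
        total_up=int(failed.sum()),
        total_cost=float(cost[failed].sum()),
        seed=seed,
        n_women=n_women,
        _cycles=np.where(failed, cycle, -1),
        _outcome_idx=outcome_idx,
        _cost=cost,
    )


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-quantity z-scores of a simulation against its expectations."""

    z_scores: dict[str, float]
    flagged: dict[str, float]  # entries with |z| > threshold
    threshold: float

    @property
    def ok(self) -> bool:
        return not self.flagged


def convergence_report(
    sim: SimResult,
    expected_events: EventCounts,
    expected_costs: CostTotals | None = None,
    cohort_size: float = 1000.0,
    threshold: float = 3.0,
) -> ConvergenceReport:
    """Compare simulated counts (and optionally cost) with cohort expectations.

    For each outcome count and the total, ``z = (observed - n p) / sqrt(n p
    (1 - p))`` with ``p`` the per-woman event probability implied by the
    expected counts (expected count / cohort size).  The total cost is
    z-scored under median (point-mass) cost sampling, where a woman's cost is
    a known function of her outcome.  Entries with ``|z| > threshold`` are
    flagged; degenerate variances (p of 0 or 1) yield z = 0 when observed
    matches expectation exactly and ``inf`` otherwise.
    """
    n = sim.n_women
    z: dict[str, float] = {}

    def zscore(observed: float, p_event: float) -> float:
        mean = n * p_event
        var = n * p_event * (1.0 - p_event)
        if var <= 0:
            return 0.0 if observed == mean else math.inf
        return (observed - mean) / math.sqrt(var)

    p_up = expected_events.total_up / cohort_size
    z["total_up"] = zscore(sim.total_up, p_up)
    for o in OUTCOME_STATES:
        z[o] = zscore(sim.counts[o], expected_events.by_outcome[o] / cohort_size)

    if expected_costs is not None:
        # Per-woman cost X = c_o with prob p_o (joint failure-and-outcome), 0 otherwise.
        c = {o: expected_costs.by_outcome[o][0] / max(expected_events.by_outcome[o], 1e-300)
             if expected_events.by_outcome[o] > 0 else 0.0
             for o in OUTCOME_STATES}
        probs = {o: expected_events.by_outcome[o] / cohort_size for o in OUTCOME_STATES}
        mean1 = sum(c[o] * probs[o] for o in OUTCOME_STATES)
        var1 = sum(c[o] ** 2 * probs[o] for o in OUTCOME_STATES) - mean1**2
        mean = n * mean1
        var = n * var1
        if var <= 0:
            z["total_cost"] = 0.0 if sim.total_cost == mean else math.inf
        else:
            z["total_cost"] = (sim.total_cost - mean) / math.sqrt(var)

    flagged = {k: v for k, v in z.items() if abs(v) > threshold}
    return ConvergenceReport(z_scores=z, flagged=flagged, threshold=threshold)
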