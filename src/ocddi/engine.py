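"""Deterministic Markov cohort engine.

Five states: one transient "on method" state and four absorbing
pregnancy-outcome states.  Each cycle a woman fails her contraceptive with
probability ``p_fail = 1 - exp(-r t)`` (annual rate ``r`` per 100
woman-years, cycle length ``t`` years) and, on failure, moves directly to an
outcome state in proportion to the outcome distribution.  No half-cycle
correction is applied: transitions are whole-cycle jumps, so the cumulative
failure probability after ``n`` cycles equals the closed form
``1 - exp(-r n t)`` exactly.

State order is fixed everywhere as ``STATES``:
(initial, birth, induced_abortion, spontaneous_abortion, ectopic_pregnancy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OUTCOME_STATES, OutcomeDistribution, RunSettings

__all__ = [
    "STATES",
    "TransitionMatrix",
    "CohortTrace",
    "EventCounts",
    "rate_to_prob",
    "build_transition_matrix",
    "run_cohort_trace",
    "expected_events",
    "closed_form_up",
    "round_display",
]

#: Fixed state order: transient state first, then the four absorbing outcomes.
STATES = ("initial",) + OUTCOME_STATES

_ROW_SUM_TOL = 1e-12


def round_display(x: float) -> int:
    """Round half away from zero, the convention used for displayed counts.

    Expected counts stay unrounded through every cost computation; this is
    applied only when a whole number of events is reported.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rate_to_prob(rate: float, t: float) -> float:
    """Convert an annual failure rate per 100 woman-years to a probability.

    Uses the constant-hazard relation ``p = 1 - exp(-r t)`` with ``r`` the
    rate per woman-year (hence the division by 100) and ``t`` the period in
    years.

    Parameters
    ----------
    rate : annual failures per 100 woman-years (Pearl index scale), >= 0.
    t : length of the period in years, > 0.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if not t > 0:
        raise ValueError(f"t must be > 0, got {t}")
    return -math.expm1(-(rate / 100.0) * t)


@dataclass(frozen=True)
class TransitionMatrix:
    """5x5 per-cycle transition matrix over ``STATES``; rows 2-5 absorbing."""

    values: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.values, dtype=float)
        if m.shape != (5, 5):
            raise ValueError(f"expected a 5x5 matrix, got shape {m.shape}")
        if (m < -_ROW_SUM_TOL).any() or (m > 1 + _ROW_SUM_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0):
            raise ValueError("every row must sum to 1")
        if not np.array_equal(m[1:], np.eye(5)[1:]):
            raise ValueError("outcome states must be absorbing (identity rows)")
        object.__setattr__(self, "values", m)

    @property
    def p_fail(self) -> float:
        return 1.0 - self.values[0, 0]


def build_transition_matrix(
    p_fail: float, outcomes: OutcomeDistribution
) -> TransitionMatrix:
    """Assemble the absorbing transition matrix for one strategy.

    The per-cycle probability of reaching outcome ``o`` is the product of the
    failure probability and the conditional outcome probability,
    ``p_fail * p_o``; with probability ``1 - p_fail`` the woman stays on her
    method.
    """
    if not (0.0 <= p_fail <= 1.0):
        raise ValueError(f"p_fail must be in [0, 1], got {p_fail}")
    bad = outcomes.violations()
    if bad:
        raise ValueError("invalid outcome distribution: " + "; ".join(map(str, bad)))
    m = np.eye(5)
    m[0, 0] = 1.0 - p_fail
    m[0, 1:] = p_fail * np.array(outcomes.as_tuple())
    return TransitionMatrix(m)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy (expected women) per cycle; row 0 is cycle 0."""

    occupancy: np.ndarray  # (n_cycles + 1, 5)
    cohort_size: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EventCounts:
    """Expected pregnancy events at the end of the horizon.

    ``by_outcome`` carries the unrounded expectations (in women); the
    ``displayed_*`` properties give the rounded whole-number forms used in
    reports.  The unrounded values are the ones fed to costing.
    """

    by_outcome: dict[str, float]

    @property
    def total_up(self) -> float:
        """Expected unintended pregnancies (sum over outcomes), unrounded."""
        return math.fsum(self.by_outcome.values())

    @property
    def displayed_by_outcome(self) -> dict[str, int]:
        return {k: round_display(v) for k, v in self.by_outcome.items()}

    @property
    def displayed_total_up(self) -> int:
        return round_display(self.total_up)

    def scaled(self, factor: float) -> "EventCounts":
        return EventCounts({k: v * factor for k, v in self.by_outcome.items()})


def run_cohort_trace(m: TransitionMatrix, settings: RunSettings) -> CohortTrace:
    """Propagate a closed cohort through ``settings.n_cycles`` cycles.

    The whole cohort starts in the transient state; each row is the previous
    row times the transition matrix.
    """
    n = settings.n_cycles
    occ = np.empty((n + 1, 5))
    occ[0] = [settings.cohort_size, 0.0, 0.0, 0.0, 0.0]
    for c in range(n):
        occ[c + 1] = occ[c] @ m.values
    return CohortTrace(occupancy=occ, cohort_size=float(settings.cohort_size))


def expected_events(trace: CohortTrace) -> EventCounts:
    """Read the expected event counts off the final cycle of the trace."""
    final = trace.occupancy[-1]
    return EventCounts(
        by_outcome={name: float(final[i + 1]) for i, name in enumerate(OUTCOME_STATES)}
    )


def closed_form_up(rate: float, settings: RunSettings) -> float:
    """Analytic expected unintended pregnancies over the horizon.

    With a single transient state and constant hazard, the cumulative
    failure probability after ``n`` cycles of length ``t`` is
    ``1 - exp(-(rate/100) n t)``; multiplied by the cohort size this must
    agree with the trace to numerical precision, which makes it an
    independent oracle for the trace computation.
    """
    p = rate_to_prob(rate, settings.n_cycles * settings.cycle_length)
    return settings.cohort_size * p
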