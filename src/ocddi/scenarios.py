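"""Scenario analyses as pure parameter transformations.

Three scenario families probe the model's assumptions without touching the
engine:

1. **Typical use** — replace the OC-alone perfect-use failure rate with the
   typical-use rate and shift every co-medication rate (point and CI bounds)
   upward by the typical-minus-perfect increment.
2. **Abortion share shift** — set the induced-abortion share of the outcome
   distribution to a target value (e.g. a state-specific share), holding the
   spontaneous-abortion and ectopic shares fixed and letting the birth share
   absorb the remainder.
3. **Age-specific outcome mixes** — re-run the model once per age-group
   outcome distribution, cohort size unchanged; since the failure dynamics do
   not depend on the outcome split, only the outcome composition and the
   costs move.

All transformations return new objects; inputs are never mutated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .config import ModelConfig, OutcomeDistribution, StrategySpec
from .costing import StrategyResult, evaluate_strategy

__all__ = [
    "ScenarioSpec",
    "typical_use_rates",
    "abortion_shift",
    "age_specific_runs",
    "scenario1_fold_change",
]

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative scenario description, parsed from a config block.

    ``kind`` is one of ``typical_use`` (needs ``typical`` and ``perfect``
    rates per 100 woman-years), ``abortion_shift`` (needs
    ``target_abortion_share``) or ``age_specific`` (needs ``mixes``, a list
    of ``(label, OutcomeDistribution)`` pairs).
    """

    kind: str
    typical: float | None = None
    perfect: float | None = None
    target_abortion_share: float | None = None
    mixes: tuple[tuple[str, OutcomeDistribution], ...] = ()

    def __post_init__(self):
        if self.kind not in ("typical_use", "abortion_shift", "age_specific"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "typical_use" and (self.typical is None or self.perfect is None):
            raise ValueError("typical_use scenario needs 'typical' and 'perfect' rates")
        if self.kind == "abortion_shift" and self.target_abortion_share is None:
            raise ValueError("abortion_shift scenario needs 'target_abortion_share'")
        if self.kind == "age_specific" and not self.mixes:
            raise ValueError("age_specific scenario needs at least one outcome mix")


def typical_use_rates(
    strategies: Sequence[StrategySpec], typical: float, perfect: float
) -> list[StrategySpec]:
    """Shift failure rates from perfect-use to typical-use conditions.

    The first strategy (OC alone) takes the typical-use rate outright; every
    other strategy's point estimate and CI bounds are increased by
    ``typical - perfect``, which preserves the printed CI widths.
    """
    if not (typical >= perfect >= 0):
        raise ValueError(
            f"need typical >= perfect >= 0, got typical={typical}, perfect={perfect}"
        )
    increment = typical - perfect
    out: list[StrategySpec] = []
    for i, s in enumerate(strategies):
        if i == 0:
            out.append(replace(s, rate_point=typical))
        else:
            out.append(
                replace(
                    s,
                    rate_point=s.rate_point + increment,
                    rate_low=None if s.rate_low is None else s.rate_low + increment,
                    rate_high=None if s.rate_high is None else s.rate_high + increment,
                )
            )
    return out


def abortion_shift(
    base: OutcomeDistribution, target_abortion_share: float
) -> OutcomeDistribution:
    """Move the induced-abortion share to ``target_abortion_share``.

    Spontaneous-abortion and ectopic shares are held at their base values;
    the birth share takes the remainder so the distribution still sums to 1.
    """
    fixed = base.spontaneous_abortion + base.ectopic_pregnancy
    if not (0.0 <= target_abortion_share and target_abortion_share + fixed <= 1.0 + _SHARE_TOL):
        raise ValueError(
            "target abortion share infeasible: "
            f"{target_abortion_share} + fixed shares {fixed} exceeds 1"
        )
    birth = 1.0 - target_abortion_share - fixed
    return OutcomeDistribution(
        birth=birth,
        induced_abortion=target_abortion_share,
        spontaneous_abortion=base.spontaneous_abortion,
        ectopic_pregnancy=base.ectopic_pregnancy,
    )


def age_specific_runs(
    mixes: Sequence[tuple[str, OutcomeDistribution]],
    cfg: ModelConfig,
    *,
    enforce_fixed_shares: bool = True,
) -> dict[str, dict[str, StrategyResult]]:
    """Evaluate every strategy under each age-group outcome mix.

    Each mix must hold the spontaneous-abortion and ectopic shares at the
    base-case values (the stated redistribution rule); pass
    ``enforce_fixed_shares=False`` to override with a warning.  Returns
    ``{label: {strategy name: point-estimate StrategyResult}}``.
    """
    base = cfg.outcomes
    results: dict[str, dict[str, StrategyResult]] = {}
    for label, mix in mixes:
        bad = mix.violations(prefix=f"mix[{label}].")
        if bad:
            raise ValueError("; ".join(map(str, bad)))
        drift = max(
            abs(mix.spontaneous_abortion - base.spontaneous_abortion),
            abs(mix.ectopic_pregnancy - base.ectopic_pregnancy),
        )
        if drift > _SHARE_TOL:
            msg = (
                f"mix {label!r} alters the spontaneous/ectopic shares "
                f"(max drift {drift:g}) which the redistribution rule holds fixed"
            )
            if enforce_fixed_shares:
                raise ValueError(msg)
            import warnings

            warnings.warn(msg, stacklevel=2)
        scenario_cfg = cfg.with_outcomes(mix)
        results[label] = {
            s.name: evaluate_strategy(s, "point", scenario_cfg)
            for s in scenario_cfg.strategies
        }
    return results


def scenario1_fold_change(cfg: ModelConfig, typical: float, perfect: float,
                          strategy_index: int = 1) -> float:
    """Fold-change in displayed UP counts for one strategy under typical use.

    Ratio of the integer-displayed unintended-pregnancy count at the shifted
    rate over the base-case displayed count, reported to one decimal — the
    convention matching published fold-changes computed from whole-number
    event counts.
    """
    shifted = typical_use_rates(cfg.strategies, typical, perfect)
    base_spec = cfg.strategies[strategy_index]
    shifted_spec = shifted[strategy_index]
    base_up = evaluate_strategy(base_spec, "point", cfg).events.displayed_total_up
    scen_up = evaluate_strategy(shifted_spec, "point", cfg).events.displayed_total_up
    if base_up == 0:
        raise ZeroDivisionError("base-case displayed UP count is zero")
    return round(scen_up / base_up, 1)
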