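"""Typed model inputs and their file I/O.

Every input the model consumes — contraceptive failure rates, the
unintended-pregnancy outcome distribution, per-outcome unit costs, the
mistimed-birth adjustment parameters and the run settings — is carried by a
small frozen dataclass with explicit invariants.  A single YAML file (see
``data/basecase.yaml`` for the shipped base case) holds one ``ModelConfig``;
unknown keys are rejected so typos cannot silently drop a parameter.

Failure rates are stored exactly as printed in the source literature, per
100 woman-years; they are divided by 100 only inside the rate-to-probability
conversion (:func:`ocddi.engine.rate_to_prob`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "OUTCOME_STATES",
    "StrategySpec",
    "OutcomeDistribution",
    "CostSummary",
    "BirthAdjustmentParams",
    "RunSettings",
    "ModelConfig",
    "Violation",
    "ConfigError",
    "load_config",
    "save_config",
    "validate_config",
    "basecase_config",
]

#: Canonical order of the four absorbing pregnancy-outcome states.
OUTCOME_STATES = (
    "birth",
    "induced_abortion",
    "spontaneous_abortion",
    "ectopic_pregnancy",
)

_PROB_SUM_TOL = 1e-9
SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised when a configuration file or object violates the schema."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which field, which rule, what was observed."""

    field: str
    rule: str
    observed: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} (observed {self.observed!r})"


@dataclass(frozen=True)
class StrategySpec:
    """A named contraceptive strategy with its annual failure rate.

    Rates are Pearl-index style: failures per 100 woman-years.  The 95% CI
    bounds are optional (the OC-alone perfect-use rate has none).
    """

    name: str
    rate_point: float
    rate_low: float | None = None
    rate_high: float | None = None

    def rate(self, variant: str = "point") -> float:
        """Return the failure rate for ``variant`` ('point', 'low', 'high')."""
        if variant == "point":
            return self.rate_point
        if variant == "low":
            if self.rate_low is None:
                raise ConfigError(f"strategy {self.name!r} has no lower CI bound")
            return self.rate_low
        if variant == "high":
            if self.rate_high is None:
                raise ConfigError(f"strategy {self.name!r} has no upper CI bound")
            return self.rate_high
        raise ConfigError(f"unknown rate variant {variant!r}")

    @property
    def variants(self) -> tuple[str, ...]:
        """Rate variants available on this strategy, 'point' first."""
        out = ["point"]
        if self.rate_low is not None:
            out.append("low")
        if self.rate_high is not None:
            out.append("high")
        return tuple(out)

    def violations(self, prefix: str = "") -> list[Violation]:
        v: list[Violation] = []
        if not self.name:
            v.append(Violation(prefix + "name", "must be non-empty", self.name))
        if self.rate_point < 0:
            v.append(Violation(prefix + "rate_point", "must be >= 0", self.rate_point))
        if (self.rate_low is None) != (self.rate_high is None):
            v.append(
                Violation(
                    prefix + "rate_low/rate_high",
                    "CI bounds must be given together",
                    (self.rate_low, self.rate_high),
                )
            )
        if self.rate_low is not None and self.rate_high is not None:
            if not (0 <= self.rate_low <= self.rate_point <= self.rate_high):
                v.append(
                    Violation(
                        prefix + "rate_low/rate_point/rate_high",
                        "must satisfy 0 <= low <= point <= high",
                        (self.rate_low, self.rate_point, self.rate_high),
                    )
                )
        return v


@dataclass(frozen=True)
class OutcomeDistribution:
    """Conditional distribution of outcomes given an unintended pregnancy."""

    birth: float
    induced_abortion: float
    spontaneous_abortion: float
    ectopic_pregnancy: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        """Probabilities in canonical ``OUTCOME_STATES`` order."""
        return (
            self.birth,
            self.induced_abortion,
            self.spontaneous_abortion,
            self.ectopic_pregnancy,
        )

    def __getitem__(self, outcome: str) -> float:
        if outcome not in OUTCOME_STATES:
            raise KeyError(outcome)
        return getattr(self, outcome)

    def violations(self, prefix: str = "outcomes.") -> list[Violation]:
        v: list[Violation] = []
        for name, p in zip(OUTCOME_STATES, self.as_tuple()):
            if not (0.0 <= p <= 1.0):
                v.append(Violation(prefix + name, "must be in [0, 1]", p))
        total = math.fsum(self.as_tuple())
        if abs(total - 1.0) > _PROB_SUM_TOL:
            v.append(Violation(prefix + "*", "must sum to 1", total))
        return v


@dataclass(frozen=True)
class CostSummary:
    """Median / min / max direct medical cost per event, 2020 USD."""

    median: float
    min: float
    max: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.median, self.min, self.max)

    def scaled(self, factor: float) -> "CostSummary":
        return CostSummary(self.median * factor, self.min * factor, self.max * factor)

    def violations(self, prefix: str = "") -> list[Violation]:
        v: list[Violation] = []
        if not (self.min > 0):
            v.append(Violation(prefix + "min", "must be > 0", self.min))
        if not (self.min <= self.median <= self.max):
            v.append(
                Violation(
                    prefix + "min/median/max",
                    "must satisfy min <= median <= max",
                    self.as_tuple(),
                )
            )
        return v


@dataclass(frozen=True)
class BirthAdjustmentParams:
    """Parameters of the mistimed-birth cost adjustment.

    A fraction ``f`` of unintended births is mistimed rather than unwanted:
    those births would have happened anyway, about ``d`` years later, so only
    the time-value of bringing the cost forward is attributed to the
    contraceptive failure.  The adjusted unit cost is
    ``cost * (1 - f / (1 + disc_rate) ** d)``.
    """

    f: float
    disc_rate: float
    d: float

    def violations(self, prefix: str = "adjustment.") -> list[Violation]:
        v: list[Violation] = []
        if not (0.0 <= self.f <= 1.0):
            v.append(Violation(prefix + "mistimed_fraction", "must be in [0, 1]", self.f))
        if self.disc_rate < 0:
            v.append(Violation(prefix + "discount_rate", "must be >= 0", self.disc_rate))
        if self.d < 0:
            v.append(Violation(prefix + "delay_years", "must be >= 0", self.d))
        return v


@dataclass(frozen=True)
class RunSettings:
    """Cohort size, cycle structure and the seed for stochastic components."""

    cohort_size: int = 1000
    cycle_length: float = 1.0 / 12.0  # years per cycle
    n_cycles: int = 12
    seed: int = 0

    @property
    def horizon_years(self) -> float:
        return self.cycle_length * self.n_cycles

    def violations(self, prefix: str = "settings.") -> list[Violation]:
        v: list[Violation] = []
        if self.cohort_size < 1:
            v.append(Violation(prefix + "cohort_size", "must be >= 1", self.cohort_size))
        if not (self.cycle_length > 0):
            v.append(Violation(prefix + "cycle_length", "must be > 0", self.cycle_length))
        if self.n_cycles < 1:
            v.append(Violation(prefix + "n_cycles", "must be >= 1", self.n_cycles))
        return v


@dataclass(frozen=True)
class ModelConfig:
    """The complete set of model inputs."""

    strategies: tuple[StrategySpec, ...]
    outcomes: OutcomeDistribution
    costs: Mapping[str, CostSummary]
    adjustment: BirthAdjustmentParams
    settings: RunSettings = field(default_factory=RunSettings)
    #: Published adjusted-birth cost summary, kept for reference only; the
    #: adjusted costing mode recomputes adjusted birth costs from `costs["birth"]`.
    birth_adjusted_published: CostSummary | None = None

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ConfigError(f"no strategy named {name!r}")

    def with_strategies(self, strategies) -> "ModelConfig":
        return replace(self, strategies=tuple(strategies))

    def with_outcomes(self, outcomes: OutcomeDistribution) -> "ModelConfig":
        return replace(self, outcomes=outcomes)

    def violations(self) -> list[Violation]:
        v: list[Violation] = []
        if not self.strategies:
            v.append(Violation("strategies", "at least one strategy required", 0))
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            v.append(Violation("strategies", "names must be unique", names))
        for i, s in enumerate(self.strategies):
            v.extend(s.violations(prefix=f"strategies[{i}]."))
        v.extend(self.outcomes.violations())
        if set(self.costs) != set(OUTCOME_STATES):
            v.append(
                Violation(
                    "costs",
                    "keys must be exactly the four outcome states",
                    sorted(self.costs),
                )
            )
        for key, cs in self.costs.items():
            v.extend(cs.violations(prefix=f"costs.{key}."))
        if self.birth_adjusted_published is not None:
            v.extend(
                self.birth_adjusted_published.violations(
                    prefix="costs.birth_adjusted_published."
                )
            )
        v.extend(self.adjustment.violations())
        v.extend(self.settings.violations())
        return v


def validate_config(cfg: ModelConfig) -> list[Violation]:
    """Return all invariant violations of ``cfg`` (empty list = valid)."""
    return cfg.violations()


# ---------------------------------------------------------------------------
# YAML (de)serialization


def _require_keys(mapping: dict, allowed: set[str], required: set[str], ctx: str):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{ctx}: unknown keys {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{ctx}: missing keys {sorted(missing)}")


def _num(value, ctx: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{ctx}: expected a number, got {value!r}")
    return float(value)


def _parse_cost(mapping, ctx: str) -> CostSummary:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{ctx}: expected a mapping with median/min/max")
    _require_keys(mapping, {"median", "min", "max"}, {"median", "min", "max"}, ctx)
    return CostSummary(
        median=_num(mapping["median"], ctx + ".median"),
        min=_num(mapping["min"], ctx + ".min"),
        max=_num(mapping["max"], ctx + ".max"),
    )


def config_from_dict(doc: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed YAML document."""
    if not isinstance(doc, dict):
        raise ConfigError("top level of config must be a mapping")
    _require_keys(
        doc,
        {"schema_version", "strategies", "outcomes", "costs", "adjustment", "settings"},
        {"schema_version", "strategies", "outcomes", "costs", "adjustment"},
        "config",
    )
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version: expected {SCHEMA_VERSION}, got {doc['schema_version']!r}"
        )

    strategies = []
    if not isinstance(doc["strategies"], list):
        raise ConfigError("strategies: expected a list")
    for i, s in enumerate(doc["strategies"]):
        ctx = f"strategies[{i}]"
        if not isinstance(s, dict):
            raise ConfigError(f"{ctx}: expected a mapping")
        _require_keys(
            s, {"name", "rate_point", "rate_low", "rate_high"}, {"name", "rate_point"}, ctx
        )
        strategies.append(
            StrategySpec(
                name=str(s["name"]),
                rate_point=_num(s["rate_point"], ctx + ".rate_point"),
                rate_low=_num(s["rate_low"], ctx + ".rate_low") if "rate_low" in s else None,
                rate_high=_num(s["rate_high"], ctx + ".rate_high") if "rate_high" in s else None,
            )
        )

    out = doc["outcomes"]
    if not isinstance(out, dict):
        raise ConfigError("outcomes: expected a mapping")
    _require_keys(out, set(OUTCOME_STATES), set(OUTCOME_STATES), "outcomes")
    outcomes = OutcomeDistribution(
        **{k: _num(out[k], f"outcomes.{k}") for k in OUTCOME_STATES}
    )

    costs_doc = doc["costs"]
    if not isinstance(costs_doc, dict):
        raise ConfigError("costs: expected a mapping")
    allowed_costs = set(OUTCOME_STATES) | {"birth_adjusted_published"}
    _require_keys(costs_doc, allowed_costs, set(OUTCOME_STATES), "costs")
    costs = {k: _parse_cost(costs_doc[k], f"costs.{k}") for k in OUTCOME_STATES}
    published = (
        _parse_cost(costs_doc["birth_adjusted_published"], "costs.birth_adjusted_published")
        if "birth_adjusted_published" in costs_doc
        else None
    )

    adj_doc = doc["adjustment"]
    if not isinstance(adj_doc, dict):
        raise ConfigError("adjustment: expected a mapping")
    _require_keys(
        adj_doc,
        {"mistimed_fraction", "discount_rate", "delay_years"},
        {"mistimed_fraction", "discount_rate", "delay_years"},
        "adjustment",
    )
    adjustment = BirthAdjustmentParams(
        f=_num(adj_doc["mistimed_fraction"], "adjustment.mistimed_fraction"),
        disc_rate=_num(adj_doc["discount_rate"], "adjustment.discount_rate"),
        d=_num(adj_doc["delay_years"], "adjustment.delay_years"),
    )

    settings = RunSettings()
    if "settings" in doc:
        s_doc = doc["settings"]
        if not isinstance(s_doc, dict):
            raise ConfigError("settings: expected a mapping")
        _require_keys(
            s_doc, {"cohort_size", "cycle_length", "n_cycles", "seed"}, set(), "settings"
        )
        settings = RunSettings(
            cohort_size=int(s_doc.get("cohort_size", settings.cohort_size)),
            cycle_length=_num(s_doc.get("cycle_length", settings.cycle_length), "settings.cycle_length"),
            n_cycles=int(s_doc.get("n_cycles", settings.n_cycles)),
            seed=int(s_doc.get("seed", settings.seed)),
        )

    cfg = ModelConfig(
        strategies=tuple(strategies),
        outcomes=outcomes,
        costs=costs,
        adjustment=adjustment,
        settings=settings,
        birth_adjusted_published=published,
    )
    problems = cfg.violations()
    if problems:
        raise ConfigError(
            "invalid configuration: " + "; ".join(str(p) for p in problems)
        )
    return cfg


def config_to_dict(cfg: ModelConfig) -> dict:
    """Inverse of :func:`config_from_dict`."""
    strategies = []
    for s in cfg.strategies:
        d = {"name": s.name, "rate_point": s.rate_point}
        if s.rate_low is not None:
            d["rate_low"] = s.rate_low
        if s.rate_high is not None:
            d["rate_high"] = s.rate_high
        strategies.append(d)
    costs = {
        k: {"median": c.median, "min": c.min, "max": c.max}
        for k, c in ((k, cfg.costs[k]) for k in OUTCOME_STATES)
    }
    if cfg.birth_adjusted_published is not None:
        p = cfg.birth_adjusted_published
        costs["birth_adjusted_published"] = {
            "median": p.median, "min": p.min, "max": p.max
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "strategies": strategies,
        "outcomes": dict(zip(OUTCOME_STATES, cfg.outcomes.as_tuple())),
        "costs": costs,
        "adjustment": {
            "mistimed_fraction": cfg.adjustment.f,
            "discount_rate": cfg.adjustment.disc_rate,
            "delay_years": cfg.adjustment.d,
        },
        "settings": {
            "cohort_size": cfg.settings.cohort_size,
            "cycle_length": cfg.settings.cycle_length,
            "n_cycles": cfg.settings.n_cycles,
            "seed": cfg.settings.seed,
        },
    }


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write ``cfg`` as YAML; ``load_config`` of the result is the identity."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def basecase_config() -> ModelConfig:
    """The base-case configuration shipped with the package."""
    ref = resources.files("ocddi").joinpath("data/basecase.yaml")
    return config_from_dict(yaml.safe_load(ref.read_text()))
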