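"""Model / Results interface.

:class:`CohortDDIModel` wraps a validated :class:`~ocddi.config.ModelConfig`;
``fit()`` evaluates every strategy at every available rate variant, forms the
two incremental comparisons of interest (enzyme inducer vs OC alone, enzyme
inducer vs enzyme neutral when those strategies exist) and returns a
:class:`CohortDDIResults` that renders the familiar seven-column results
table and exports CSV/markdown.  Stochastic validation hangs off the model
via :meth:`CohortDDIModel.simulate`.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .config import (
    OUTCOME_STATES,
    ModelConfig,
    basecase_config,
    config_to_dict,
    load_config,
)
from .costing import (
    IncrementalResult,
    StrategyBundle,
    StrategyResult,
    compare_strategies,
    evaluate_strategy_bundle,
)
from .engine import round_display

__all__ = ["CohortDDIModel", "CohortDDIResults"]

_OUTCOME_LABELS = {
    "birth": "births",
    "induced_abortion": "induced abortions",
    "spontaneous_abortion": "spontaneous abortions",
    "ectopic_pregnancy": "ectopic pregnancies",
}


def _fmt_range(triple: tuple[float, float, float]) -> str:
    med, lo, hi = (round_display(x) for x in triple)
    return f"{med:,} ({lo:,}-{hi:,})"


@dataclass(frozen=True)
class CohortDDIResults:
    """Fitted results: per-strategy/variant evaluations plus incrementals."""

    config: ModelConfig
    bundles: dict[str, StrategyBundle]
    incrementals: list[IncrementalResult]
    config_hash: str

    # -- access ------------------------------------------------------------

    def strategy(self, name: str, variant: str = "point") -> StrategyResult:
        return self.bundles[name].results[variant]

    def incremental(self, comparator: str, reference: str) -> IncrementalResult:
        for inc in self.incrementals:
            if inc.comparator == comparator and inc.reference == reference:
                return inc
        a, b = self.bundles[comparator], self.bundles[reference]
        return compare_strategies(a, b)

    @property
    def columns(self) -> list[StrategyResult]:
        """Table columns: each strategy's variants in point/low/high order."""
        cols = []
        for bundle in self.bundles.values():
            for variant in ("point", "low", "high"):
                if variant in bundle.results:
                    cols.append(bundle.results[variant])
        return cols

    # -- rendering ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-form numeric table: one row per (strategy, variant, quantity)."""
        rows = []
        for r in self.columns:
            base = {"strategy": r.strategy, "variant": r.variant, "rate": r.rate}
            for o in OUTCOME_STATES:
                rows.append(
                    base
                    | {
                        "quantity": f"n_{o}",
                        "median": r.events.by_outcome[o],
                        "min": r.events.by_outcome[o],
                        "max": r.events.by_outcome[o],
                    }
                )
                for mode in ("unadjusted", "adjusted"):
                    med, lo, hi = r.costs(mode).by_outcome[o]
                    rows.append(
                        base
                        | {"quantity": f"cost_{o}_{mode}", "median": med, "min": lo, "max": hi}
                    )
            rows.append(
                base
                | {
                    "quantity": "n_unintended_pregnancies",
                    "median": r.events.total_up,
                    "min": r.events.total_up,
                    "max": r.events.total_up,
                }
            )
            for mode in ("unadjusted", "adjusted"):
                med, lo, hi = r.costs(mode).total
                rows.append(
                    base | {"quantity": f"cost_total_{mode}", "median": med, "min": lo, "max": hi}
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        """Display table mirroring the published layout.

        Count rows are integers (rounded half away from zero); cost rows are
        ``median (min-max)`` strings rounded to the nearest dollar.
        """
        cols = {}
        for r in self.columns:
            label = f"{r.strategy} [{r.variant}: {r.rate:g}]"
            cells = {}
            for o in OUTCOME_STATES:
                name = _OUTCOME_LABELS[o]
                cells[f"Number of {name} (n)"] = str(r.events.displayed_by_outcome[o])
                cells[f"Cost of {name}, unadjusted (USD), median (range)"] = _fmt_range(
                    r.costs_unadjusted.by_outcome[o]
                )
                if o == "birth":
                    cells["Cost of births, adjusted (USD), median (range)"] = _fmt_range(
                        r.costs_adjusted.by_outcome[o]
                    )
            cells["Total unintended pregnancies (n)"] = str(r.events.displayed_total_up)
            cells["Total cost, unadjusted (USD), median (range)"] = _fmt_range(
                r.costs_unadjusted.total
            )
            cells["Total cost, adjusted (USD), median (range)"] = _fmt_range(
                r.costs_adjusted.total
            )
            cols[label] = cells
        return pd.DataFrame(cols)

    def incremental_frame(self) -> pd.DataFrame:
        rows = []
        for inc in self.incrementals:
            rows.append(
                {
                    "comparator": inc.comparator,
                    "reference": inc.reference,
                    "additional unintended pregnancies": inc.delta_up,
                    "additional cost, unadjusted (USD)": _fmt_range(inc.delta_cost_unadjusted),
                    "additional cost, adjusted (USD)": _fmt_range(inc.delta_cost_adjusted),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report: results table plus incremental burden."""
        buf = io.StringIO()
        buf.write("Markov cohort model of unintended pregnancies due to OC DDIs\n")
        s = self.config.settings
        buf.write(
            f"cohort: {s.cohort_size} women, {s.n_cycles} cycles of "
            f"{s.cycle_length:.6g} years; config hash {self.config_hash[:12]}\n\n"
        )
        buf.write(self.summary_frame().to_markdown())
        buf.write("\n\nCounts are rounded half away from zero for display; costs are\n")
        buf.write("computed from unrounded expected counts and rounded to the dollar.\n")
        if self.incrementals:
            buf.write("\nIncremental burden (comparator minus reference, bound for bound):\n")
            buf.write(self.incremental_frame().to_markdown(index=False))
            buf.write("\n")
        return buf.getvalue()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def to_markdown(self) -> str:
        return self.summary()

    def write_outputs(self, out_dir, fmt: str = "both") -> list[Path]:
        """Write table outputs under ``out_dir``; returns the paths written."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        if fmt in ("csv", "both"):
            p = out_dir / "results.csv"
            self.to_csv(p)
            written.append(p)
            p = out_dir / "incrementals.csv"
            self.incremental_frame().to_csv(p, index=False)
            written.append(p)
        if fmt in ("markdown", "both"):
            p = out_dir / "results.md"
            p.write_text(self.summary())
            written.append(p)
        meta = out_dir / "run_metadata.json"
        meta.write_text(
            json.dumps(
                {"config_hash": self.config_hash, "seed": self.config.settings.seed},
                indent=2,
            )
        )
        written.append(meta)
        return written


@dataclass
class CohortDDIModel:
    """Markov cohort model of unintended pregnancies under DDI exposure.

    Parameters
    ----------
    config : ModelConfig
        Validated model inputs (strategies, outcome distribution, unit costs,
        mistimed-birth adjustment, run settings).

    Examples
    --------
    >>> from ocddi import CohortDDIModel
    >>> res = CohortDDIModel.basecase().fit()
    >>> res.strategy("OC + enzyme inducer").events.displayed_total_up
    23
    """

    config: ModelConfig
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "CohortDDIModel":
        return cls(config=load_config(path))

    @classmethod
    def basecase(cls) -> "CohortDDIModel":
        return cls(config=basecase_config())

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(config_to_dict(self.config), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def _default_comparisons(self) -> list[tuple[str, str]]:
        names = [s.name for s in self.config.strategies]
        if len(names) < 2:
            return []
        pairs = [(names[1], names[0])] if len(names) >= 2 else []
        if len(names) >= 3:
            pairs.append((names[1], names[2]))
        return pairs

    def fit(self) -> CohortDDIResults:
        """Evaluate every strategy/variant and the incremental comparisons."""
        bundles = {
            s.name: evaluate_strategy_bundle(s, self.config)
            for s in self.config.strategies
        }
        pairs = self.comparisons or self._default_comparisons()
        incrementals = [
            compare_strategies(bundles[a], bundles[b]) for a, b in pairs
        ]
        return CohortDDIResults(
            config=self.config,
            bundles=bundles,
            incrementals=incrementals,
            config_hash=self.config_hash,
        )

    def simulate(self, strategy: str, variant: str = "point", n_women: int | None = None,
                 seed: int | None = None, cost_sampling: str = "median"):
        """Run the individual-level microsimulation for one strategy.

        Thin delegate to :func:`ocddi.microsim.simulate_cohort`; see there
        for the sampling rules.
        """
        from .microsim import simulate_cohort

        spec = self.config.strategy(strategy)
        return simulate_cohort(
            self.config,
            spec,
            variant=variant,
            n_women=n_women if n_women is not None else self.config.settings.cohort_size,
            seed=seed if seed is not None else self.config.settings.seed,
            cost_sampling=cost_sampling,
        )
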