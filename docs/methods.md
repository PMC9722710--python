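# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort model with five states: one
transient state ("on method", non-pregnant) and four absorbing states
(birth, induced abortion, spontaneous abortion, ectopic pregnancy). A
closed cohort of `cohort_size` women starts entirely in the transient state
and is propagated for `n_cycles` cycles of `cycle_length` years (base case:
1,000 women, 12 monthly cycles). Assumptions:

- **Constant hazard.** The annual failure rate `r` (per 100 woman-years,
  Pearl-index scale) is constant over the horizon; the per-cycle failure
  probability is `p = 1 − exp(−(r/100)·t)`.
- **Outcome at failure.** A woman who fails moves directly to her terminal
  outcome state in the failure cycle; gestation timing is not modelled, and
  she never re-enters (no switching, discontinuation or repeat pregnancy).
- **Cycle-invariant outcome split.** The conditional outcome distribution
  (0.492 / 0.350 / 0.153 / 0.005) is the same every cycle, so at any cycle
  the absorbing occupancies are in exactly these proportions — a property
  the tests exploit.
- **No half-cycle correction.** Transitions are whole-cycle jumps, so the
  cumulative failure probability after `n` cycles equals the closed form
  `1 − exp(−(r/100)·n·t)` exactly. This analytic expression doubles as an
  independent oracle for the trace (`closed_form_up`), and the equivalence
  is enforced to 1e−9 relative tolerance by property tests.
- **All pregnancies unintended.** Within the one-year horizon every
  pregnancy is counted as unintended; fertility heterogeneity is ignored.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| failure rate, OC alone | 0.3 | per 100 woman-years | perfect use; no CI |
| failure rate, OC + enzyme inducer | 2.3 (1.9–2.8) | per 100 woman-years | claims-based real-world estimate |
| failure rate, OC + enzyme neutral | 1.6 (1.4–1.8) | per 100 woman-years | claims-based real-world estimate |
| outcome split (birth/IA/SA/EP) | 0.492 / 0.350 / 0.153 / 0.005 | probability | conditional on unintended pregnancy |
| unit costs | see `basecase.yaml` | 2020 USD per event | median (min–max) across payer sources |
| mistimed fraction `f` | 0.60 | — | share of unintended births merely mistimed |
| discount rate | 0.03 | per year | used only inside the mistimed-birth adjustment |
| delay `d` | 2 | years | assumed delay of a mistimed birth |
| cohort size | 1000 | women | |
| cycles | 12 × 1/12 year | | one-year horizon |

Rates are stored exactly as printed (per 100 woman-years) and divided by
100 only inside `rate_to_prob`, so the configuration file mirrors the
published input table literally.

## Costing conventions

Cost totals are unrounded expected counts times unit costs, with the
median, minimum and maximum propagated independently (deterministic
interval propagation: min with min, max with max; for CI-bearing
strategies, the minimum total is evaluated at the lower-CI rate and the
maximum at the upper-CI rate). These are bounding scenarios, not
probabilistic intervals. No within-horizon discounting is applied; the 3%
rate exists solely inside the mistimed-birth adjustment.

The adjusted costing mode applies `cost × (1 − f/(1+r)^d)` to each birth
unit-cost bound (giving ≈5,627 / 2,290 / 12,453 from 12,953 / 5,270 /
28,664). The separately published adjusted-birth *median* summary (5,497)
is not the formula applied to 12,953 — it plausibly summarizes
individually adjusted source costs — and is therefore retained in the
configuration as `birth_adjusted_published` for reference only; all
computed adjusted results use the formula, which is the convention
consistent with the published results table.

Incremental comparisons subtract corresponding bounds. The displayed
pregnancy difference is the difference of the integer-displayed counts
(here identical to rounding the difference of unrounded counts).

## Numerical conventions

- **Display rounding** is half away from zero, applied only at the
  reporting boundary; every cost computation uses unrounded expectations.
  This is why an ectopic-pregnancy count can display as 0 while its cost
  total is non-zero.
- **Tolerances.** Trace-vs-closed-form equivalence: 1e−9 relative. Row
  stochasticity of the transition matrix: 1e−12. Outcome-probability sum:
  1e−9. Reproduction checks against published dollar cells: 0.1% relative
  plus $0.50 absolute, because the published cells are rounded to the
  nearest dollar and the smallest cells (a few hundred dollars) carry
  rounding error above 0.1% of their magnitude.
- **Degenerate inputs.** Zero rates produce an identity transition matrix
  and zero events/costs; per-cycle probability 1 absorbs the whole cohort
  in cycle 1; `f = 0` leaves birth costs unchanged.
- **State order** is fixed everywhere as (initial, birth, induced_abortion,
  spontaneous_abortion, ectopic_pregnancy).

## Scenarios

1. **Typical use.** The OC-alone rate is replaced by the typical-use rate
   (7.2) and each co-medication rate — point estimate and both CI bounds —
   is increased by the typical-minus-perfect increment (6.9), preserving CI
   widths. The reported fold-change in unintended pregnancies is the ratio
   of integer-displayed counts, reported to one decimal (88/23 = 3.8;
   unrounded counts would give 3.87 — the whole-number convention matches
   the published figure and is the one adopted).
2. **Abortion-share shift.** The induced-abortion share is set to a target
   value (e.g. a state-specific share); spontaneous-abortion and ectopic
   shares are held at base values and the birth share absorbs the
   remainder. The hold-constant redistribution rule is stated for the
   age-specific scenario and applied here as well, as the only stated
   mechanism.
3. **Age-specific mixes.** One full evaluation per age-group outcome
   distribution at fixed cohort size; mixes must hold the
   spontaneous/ectopic shares at base values (overridable with a warning).

State-specific abortion shares and age-specific outcome mixes are external
inputs not shipped with the package; scenarios 2–3 are therefore covered by
their structural invariants (total unintended pregnancies is invariant
under any outcome-mix change; the redistributed distribution sums to 1)
rather than by value reproduction.

## Synthetic cohorts and the stochastic oracle

`simulate_cohort` draws individual women independently: time to failure is
geometric with the engine's per-cycle probability (drawn by inverse CDF
from one uniform per woman), outcome is categorical, and each event gets a
unit cost — a point mass at the median by default, matching the
deterministic median pathway, or optionally triangular(min, median, max) as
an exploratory extension. Randomness comes from a counter-based Philox
generator keyed by the seed with all draws made as whole arrays, so results
are bit-reproducible and independent of iteration order.

This generator emulates exactly the cohort model's assumptions — constant
hazard, immediate outcome, independence, no switching — and none of the
features of real claims data (adherence dynamics, dose-dependent induction,
seasonal dispensing, cost skew). Agreement between the simulator and the
cohort trace therefore validates the arithmetic of both implementations
(double coding), not the model's external validity.

`convergence_report` z-scores each simulated count against its
binomial/multinomial expectation and flags |z| > 3. The acceptance-level
check runs 500,000 women (well under a second, vectorized), requiring the
simulated failure proportion within 3 binomial standard errors of
`1 − exp(−0.023)` and a chi-square outcome goodness-of-fit p > 0.01 at the
shipped seed; cohort sizes 10³–5·10⁵ are exercised in the unit tests.

## Design choices that were genuinely open

- **Rounding rule for displayed counts** is unstated in the source
  (11.19→11 and 3.48→3 are consistent with several rules); half away from
  zero is adopted and documented.
- **ΔUP from rounded vs unrounded counts** both give 20 (and 7) here;
  the rounded-count difference is used for display consistency.
- **Configuration schema** is this package's own convention (YAML,
  `schema_version`, unknown-key rejection); no machine-readable schema was
  published.

## Limitations

Constant failure rates ignore heterogeneity in perpetrator drug, dose and
adherence; adverse-event, indirect, downstream and societal costs are out
of scope, as are contraceptive switching and discontinuation; cost ranges
are bounding intervals, not confidence intervals; and the one-year horizon
precludes repeat pregnancies. These mirror the boundaries of the analysis
the model reproduces.
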