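# Methods

## Model structure

`apseq` is a deterministic Markov cohort model with a 6-week (42-day) cycle,
tracking the fraction of a treatment cohort across an ordered sequence of
antipsychotic lines. For a sequence of L drugs the state space has 5L + 1
states: per line, *stable first cycle*, *stable continuing*, *no treatment*,
*relapse from stable* and *relapse from no treatment*, plus one absorbing
*dead* state. The horizon is `floor(365.25 × years / 42)` whole cycles
(43 cycles for five years, 26 for three), chosen as the unambiguous rounding
rule; the cohort ages 42/365.25 years per cycle.

Each cycle applies, in order:

1. **Death.** The general-population annual death probability at the cohort's
   current age (abridged life table, step lookup, clamped at both ends) is
   multiplied by the schizophrenia standardised mortality ratio (default 2.6,
   capped at probability 1) and converted to a per-cycle probability under
   constant-rate (exponential) equivalence with a 365.25-day year. All other
   events apply to the survivors, giving one consistent competing-risk
   ordering.
2. **Treatment events.** On-treatment states exit via adverse-event (AE)
   discontinuation (first cycle on a drug only — intolerable side effects
   reveal themselves on initiation; the patient switches to the next line),
   other-reason discontinuation (second cycle onward by default; the patient
   stops abruptly into *no treatment*), or relapse. The three probabilities
   are validated to sum to at most 1; the remainder stays stable. The
   no-treatment state exits only via relapse (7.1%/cycle default, the placebo
   rate) or death — discontinuers cannot relapse within the cycle in which
   they stop.
3. **Relapse resolution.** A relapse ends the current drug. The episode is
   treated acutely (six-weekly acute-care cost plus olanzapine 10 mg/day
   replacing the prior drug's cost) and the patient then moves to the next
   line of the sequence. On the last line the patient restarts the same drug;
   when the next line is age-gated (see below) the patient waits untreated.

### Mid-cycle timing and relapse duration

All transitions are assumed to occur in the middle of a cycle. Under the
default `relapse_resolution="within_cycle"`, a relapse episode therefore
spans the half cycle between the mid-cycle transition and the next boundary:
costing charges half a cycle at the origin state's rates and half at the
relapse state's rates, and the destination treatment is occupied from the
next cycle. The alternative `"full_cycle"` holds the cohort in the relapse
state for one whole cycle before resolving. The within-cycle reading follows
from the mid-cycle transition convention and is the rule set under which the
model reproduces the published base-case relapse counts this implementation
was built against (see *Structural identification* below).

### Age gating

Licensing minimum ages gate each drug (`min_age`): in the bundled adolescent
sequences, aripiprazole and paliperidone cannot be received before age 15.
Under the default `gate_mode="strict"` the sequence is taken strictly in
order and a patient whose next line is still gated waits in the no-treatment
state (relapsing there at the no-treatment rate) until the cohort reaches the
licensing age; `"skip"` instead jumps to the next licensed drug further down
the sequence.

### Re-initiation semantics

Two readings exist for a relapse occurring off treatment. The default
(`nt_relapse_destination="advance"`) deems the stopped drug unsuccessful and
moves the patient to the next line. The alternative (`"return"`) re-initiates
the same drug; in that mode `reapply_first_cycle_on_reinitiation` controls
whether first-cycle AE risk (and one-off AE costs) apply again — default
off, since the drug was previously tolerated. Returning to any drug after at
least one untreated cycle incurs the medication-switching cost
(`charge_switch_on_reinitiation`, default on).

### Structural identification

The pathway rules above contain four genuinely open choices (relapse
duration, no-treatment relapse destination, first-cycle other-reason
discontinuation, gate overflow). The defaults were fixed by requiring the
model, run on the bundled published inputs, to reproduce the reported
base-case per-patient relapse counts of the analysis it re-implements; the
within-cycle/advance/no-first-cycle-other rule set reproduces the adult
(2.399/2.425 vs 2.407/2.456 reported) and 15–17 (1.198/1.278 vs 1.214/1.297)
cohorts to the third decimal, including the arm differences, where the
alternative readings err by up to an order of magnitude more. Every rejected
reading remains available as a `ModelOptions` switch, and the cohort engine
and the microsimulation oracle implement all of them independently.

## Inputs and parameters

* **Drug profiles** (per drug): daily dose (mg/day), pack price (GBP), pack
  content (mg), six-weekly probabilities of AE discontinuation, other-reason
  discontinuation and relapse, one-off probabilities of ≥7% weight gain and
  EPS, a monitoring flag (clozapine) and a licensing age. Clozapine's AE
  discontinuation has no source estimate; it is stored as exactly 0 with a
  provenance flag and is excluded from sensitivity analysis.
* **Populations**: start age (13 / 15 / 18 — the adult entry age is a
  convention, configurable), horizon (5 / 3 / 5 years), intervention and
  comparator sequences, no-treatment relapse (0.071/cycle), SMR (2.6) and a
  cost block.
* **Costs** (GBP, 2019/20 prices): six-weekly stable and relapse health-state
  aggregates (adults £2,000 / £27,906; adolescents £701 / £28,692), one-off
  AE costs (£92 weight gain, £220 EPS), and three components whose published
  sources describe resource use without printing unit totals — these are
  required configuration fields with documented, user-replaceable fixture
  defaults flagged as calibration knobs: medication switching £687 (three
  consultant-psychiatrist visits at ≈£229), clozapine monitoring £9/cycle
  (≈three blood tests at ≈£3), and olanzapine 10 mg/day at £0.05/day
  (generic pricing). The no-treatment state carries the stable-state resource
  aggregate with zero drug cost (clinically "stable, untreated"); this is
  calibration-sensitive and configurable. Discounting defaults to 0 (the
  reference analysis applies none) and can be switched on (e.g. 3.5%/year),
  applied per cycle at `(1+r)^(−t·42/365.25)`. A single multiplicative
  `inflation_factor` is the only price-adjustment mechanism.
* **Life table**: the bundled table is a synthetic UK-style abridged table
  (5-year bands; labelled synthetic in its filename) standing in for national
  norms, which the sources cite without printing. Over 3–5 year horizons with
  adolescent/young-adult rates, mortality contributes at the third decimal of
  relapse counts; users can substitute any `age,q_annual` CSV.

## Derivation utilities

Published comparative estimates arrive as odds ratios (discontinuation) or
relative risks (relapse) against placebo and as annual rates. The converters
follow standard decision-modelling practice: OR applied on the reference
odds and converted back (`odds/(1+odds)`); RR as a capped product; annual ↔
cycle conversion by constant-rate equivalence (exact round-trip to 1e−12).
Daily drug cost is linear in milligrams (`pack_price × dose / pack_mg`,
fractional tablets pro rata) — the only pricing rule consistent with all
seven published daily costs (e.g. one 74 mg-tablet pack pricing both the
80 mg and 148 mg lurasidone doses) — and is carried unrounded through the
model, rounded to pence only for display.

## Costing

State costs follow the mid-cycle rule: each cycle is costed at the average of
its start- and end-of-boundary occupancy (equivalently: stayers a full
cycle, movers half origin + half destination; deaths half origin), with a
correction term for within-cycle relapse episodes as described above.
Switching costs apply per line advance and per re-initiation; one-off AE
costs apply to first-ever initiation flows per drug (model entry included).
The ledger keeps eight categories (drug, monitoring, stable state,
no-treatment state, relapse state, switching, weight-gain AE, EPS AE); the
grand total is their exact sum, and scales exactly linearly with joint
scaling of all unit costs.

## Sensitivity analysis

* **One-way DSA**: every drug probability, pack price, cost field and the
  no-treatment relapse probability is varied one at a time between its
  bounds — explicit 95% intervals when configured, otherwise ±20% clamped to
  the parameter's domain — and entries are ranked by the induced range in
  incremental cost (ties broken lexicographically by parameter id).
* **PSA**: probabilities are sampled by applying a median-1 log-normal
  multiplier on the odds scale (preserving [0,1]); σ comes from a 95%
  interval when given, else from CV = SE/central with SE defaulting to 25%
  of the central value. Costs and other money parameters are gamma draws
  moment-matched to (mean, SE). If a drug's sampled competing probabilities
  sum above 1 the triple is rescaled proportionally (a rare event at the
  default spreads). Each parameter draws from its own substream, derived
  deterministically from the master seed and a hash of the parameter id, so
  adding or removing a parameter never perturbs the other draws; a degenerate
  all-fixed PSA reproduces the base case bit-for-bit.

## Synthetic data and cross-validation

`synthetic.random_parameter_set` generates structurally valid random models:
uniform draws within configurable ranges for all probabilities (ranges
guarantee the competing-risk row sum stays below 1 by construction), prices,
dosing and costs, a random monitoring flag, and a single population whose
comparator arm is the reversed sequence. Defaults (3 drugs, 3-year horizon,
start age 30, no age gates) are a deliberately mid-sized condition; the
generator emulates the *shape* of the real inputs, not their correlation
structure, dose–response relationships or age licensing, so passing
equivalence tests demonstrate correctness of the pathway mechanics rather
than clinical realism.

The microsimulation oracle (`microsim.microsimulate`) is an independent
straight-line per-patient implementation of the same rules — categorical
draws per patient-cycle, Bernoulli AE one-offs, identical cost conventions —
sharing no transition machinery with the engine. The repository's headline
equivalence test runs 20 random parameter sets at 50,000 patients each and
requires cohort expectations to sit within 3 Monte-Carlo standard errors of
the microsimulation means for relapse counts, total cost and time in every
state; at these sizes the false-failure probability is negligible and the
whole suite runs in well under a minute.

## Numerical choices

Occupancy conservation is enforced at 1e−10 per cycle and the dead fraction
is checked monotone; transition tables are cached per (death-probability,
gate-pattern) key, so a full 43-cycle three-population base case runs in
~15 ms. Probabilities applied through the parameter registry are clamped to
[0,1] and competing triples renormalised only when they would exceed 1.
Configuration parsing is strict: unknown keys anywhere raise a named error,
and a saved configuration reloads bit-for-bit.

## Known limitations

* The reported base-case relapse counts for the 13–17 cohort (2.669/2.781)
  are **not** reproduced: every structural reading explored yields ≈2.20–2.30.
  Reaching the reported values would require an average relapse rate of
  0.062/cycle over 43 cycles from a fresh treated cohort, while with the
  published no-treatment relapse probability of 0.071/cycle the model's
  attainable ceiling is ≈0.053/cycle (untreated occupancy cannot exceed
  ≈80%). The inputs that would close the gap (e.g. under-15-specific relapse
  inputs, or a no-treatment rate near 0.11/cycle) are not published at this
  level of detail; the bundled fixture keeps the printed values.
* Absolute per-patient totals depend on the unprinted cost components
  (switching, monitoring, acute-episode drug) and on the no-treatment
  costing convention; the cost *direction* and the dominance of
  relapse-related savings are robust across these knobs, and only those are
  asserted.
* Under uniform ±20% DSA bounds the adolescent tornado is led by
  haloperidol's relapse probability rather than lurasidone's other-reason
  discontinuation (which leads for adults); wide NMA-style credible
  intervals, where available, would change that ranking.
* No quality-of-life weighting or QALYs: this is a cost and relapse-count
  model only. No individual-level heterogeneity in the cohort engine (the
  microsimulation exists for validation, not inference), no variance
  reduction, and no treatment-effect waning across lines.
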