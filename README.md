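# apseq — antipsychotic sequencing cost model

`apseq` is a Markov cohort model of antipsychotic treatment *sequences* in
schizophrenia, built to quantify the cost impact of giving lurasidone
first-line rather than later in the pathway. It re-implements, as a tested and
configurable Python pipeline, a published UK cost analysis comparing
lurasidone-first sequences against clinician-elicited comparator sequences in
three cohorts: adolescents aged 13–17 (5-year horizon), adolescents aged 15–17
(3-year horizon) and adults (5-year horizon).

The model is for health-economics practitioners and methodologists: every
clinical input (six-weekly discontinuation, relapse and adverse-event
probabilities per drug; pack prices; health-state cost aggregates) is a
configuration value, every structural rule the sources leave open is an
explicit option, and an independent patient-level microsimulation oracle
cross-validates the cohort engine.

## The model

A cohort enters on the first drug of an ordered, age-gated sequence and is
tracked in 6-week (42-day) cycles. Each treatment line contributes five
states — first cycle on drug, stable continuing, no treatment, and two acute
relapse states (from stable, from no treatment) — plus one absorbing death
state. Per cycle, in competing order:

* death first, at the age-specific general-population probability scaled by a
  standardised mortality ratio (SMR 2.6), converted to a per-cycle
  probability by constant-rate equivalence `1 − (1 − q)^(42/365.25)`;
* on treatment: discontinuation due to intolerable adverse events (first
  cycle of use only, leading to a switch to the next line), discontinuation
  for other reasons (second cycle onward, leading to no treatment), or
  relapse;
* off treatment: relapse at the placebo rate (7.1% per cycle, from a 47.3%
  annual rate).

A relapse episode stops the current drug, costs one acute-care six-weekly
aggregate plus olanzapine 10 mg/day, and resolves into the next line of the
sequence (restarting the current drug on the last line, or waiting untreated
while the next line is still age-gated). All transitions occur mid-cycle and
costs follow the matching half-cycle rule. Costs are GBP per patient across
four categories: drug acquisition (linear-in-mg pricing, plus clozapine
monitoring), medication switching, health-state aggregates, and one-off
adverse-event management (≥7% weight gain, EPS) applied at first initiation
of each drug.

Sensitivity analysis mirrors standard practice: one-way DSA over every
clinical and cost parameter (95% intervals where supplied, ±20% otherwise)
ranked into a tornado ordering, and PSA with log-normal sampling of
probabilities on the log-odds scale and gamma sampling of costs
(SE = 25% of the mean by default), with per-parameter random substreams so
results are reproducible parameter-by-parameter.

## Worked example

```python
import apseq

cfg = apseq.fixture_base_case()          # bundled drug/cost/population inputs
lifetable = apseq.load_life_table()
results = apseq.run_base_case(cfg, lifetable)
for label, r in results.items():
    print(f"{label}: relapses {r.relapses_intervention:.3f} vs "
          f"{r.relapses_comparator:.3f} (diff {r.relapse_difference:+.3f}), "
          f"incremental cost {r.cost_difference:+,.0f} GBP")
```

prints

```
adolescent_13_17: relapses 2.204 vs 2.234 (diff -0.030), incremental cost -295 GBP
adolescent_15_17: relapses 1.198 vs 1.278 (diff -0.080), incremental cost -792 GBP
adult: relapses 2.399 vs 2.425 (diff -0.026), incremental cost -86 GBP
```

i.e. lurasidone first-line yields fewer expected relapses per patient and is
cost-saving in all three cohorts: the extra acquisition and stable-state
costs are outweighed by relapse-related savings. The same analyses are
available from the shell:

```sh
apseq run --out out/                 # base case, all populations
apseq dsa --population adult --out out/
apseq psa --n 1000 --seed 42 --out out/
apseq validate --oracle-n 50000      # engine vs microsimulation cross-check
```

Configurations are YAML with top-level keys `drugs`, `populations`,
`options`, `uncertainty`; see `src/apseq/data/base_case.yaml` for the
documented schema and `docs/methods.md` for the modelling choices, structural
options and their rationale.

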