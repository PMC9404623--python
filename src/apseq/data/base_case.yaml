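# Base-case model configuration: UK antipsychotic sequencing cost model.
#
# Six-weekly event probabilities and pack pricing per drug, the three modelled
# cohorts with their arm sequences, and population-level cost inputs.
# Probabilities are per 6-week cycle; p_weight_gain / p_eps are one-off
# first-cycle probabilities. Costs are GBP (2019/20 price year).
#
# Fields marked "unprinted - calibration knob" are required model inputs whose
# published sources report only resource-use descriptions, not unit totals;
# the defaults here are documented in docs/methods.md and are user-replaceable.

drugs:
  lurasidone_adolescent:          # 80 mg/day
    daily_dose: 80.0
    pack_price: 90.72
    pack_total_mg: 2072.0         # 28 x 74 mg tablets
    p_disc_ae: 0.013
    p_disc_other: 0.088
    p_relapse: 0.021
    p_weight_gain: 0.059
    p_eps: 0.287
    min_age: 13.0
  haloperidol:                    # 3 mg/day
    daily_dose: 3.0
    pack_price: 4.48
    pack_total_mg: 100.0          # 5 mg/5 ml oral solution, 100 ml
    p_disc_ae: 0.080
    p_disc_other: 0.075
    p_relapse: 0.049
    p_weight_gain: 0.097
    p_eps: 0.462
    min_age: 13.0
  paliperidone:                   # 6 mg/day
    daily_dose: 6.0
    pack_price: 97.28
    pack_total_mg: 168.0          # 28 x 6 mg tablets
    p_disc_ae: 0.034
    p_disc_other: 0.038
    p_relapse: 0.019
    p_weight_gain: 0.147
    p_eps: 0.238
    min_age: 15.0
  aripiprazole:                   # 10 mg/day
    daily_dose: 10.0
    pack_price: 0.59
    pack_total_mg: 140.0          # 28 x 5 mg tablets
    p_disc_ae: 0.153
    p_disc_other: 0.257
    p_relapse: 0.046
    p_weight_gain: 0.090
    p_eps: 0.195
    min_age: 15.0
  lurasidone_adult:               # 148 mg/day
    daily_dose: 148.0
    pack_price: 90.72
    pack_total_mg: 2072.0         # 28 x 74 mg tablets
    p_disc_ae: 0.076
    p_disc_other: 0.182
    p_relapse: 0.021
    p_weight_gain: 0.059
    p_eps: 0.287
    min_age: 18.0
  brexpiprazole:                  # 4 mg/day
    daily_dose: 4.0
    pack_price: 104.47            # assumed 30% above cariprazine
    pack_total_mg: 168.0          # 28 x 6 mg tablets
    p_disc_ae: 0.056
    p_disc_other: 0.256
    p_relapse: 0.025
    p_weight_gain: 0.135
    p_eps: 0.237
    min_age: 18.0
  cariprazine:                    # 6 mg/day
    daily_dose: 6.0
    pack_price: 80.36
    pack_total_mg: 168.0          # 28 x 6 mg tablets
    p_disc_ae: 0.085
    p_disc_other: 0.288
    p_relapse: 0.037
    p_weight_gain: 0.056
    p_eps: 0.327
    min_age: 18.0
  clozapine:                      # 325 mg/day; last line in every sequence
    daily_dose: 325.0
    pack_price: 6.32
    pack_total_mg: 2100.0         # 84 x 25 mg tablets
    p_disc_ae: 0.0                # source reports no figure ("NA")
    disc_ae_unavailable: true
    p_disc_other: 0.054
    p_relapse: 0.049
    p_weight_gain: 0.333
    p_eps: 0.068
    requires_monitoring: true
    min_age: 13.0

populations:
  adolescent_13_17:
    start_age: 13.0
    horizon_years: 5.0
    cycle_length_days: 42.0
    sequence: [lurasidone_adolescent, haloperidol, aripiprazole, paliperidone, clozapine]
    comparator_sequence: [haloperidol, lurasidone_adolescent, aripiprazole, paliperidone, clozapine]
    no_treatment_relapse: 0.071
    smr: 2.6
    costs: &adolescent_costs
      stable_state_cost: 701.0
      relapse_state_cost: 28692.0
      ae_weight_gain_cost: 92.0
      ae_eps_cost: 220.0
      switching_cost: 687.0           # unprinted - calibration knob: 3 consultant psychiatrist visits @ ~GBP 229
      monitoring_cost_per_cycle: 9.0  # unprinted - calibration knob: ~3 blood tests per cycle @ ~GBP 3
      relapse_drug_daily_cost: 0.05   # unprinted - calibration knob: generic olanzapine 10 mg/day
      discount_rate: 0.0
  adolescent_15_17:
    start_age: 15.0
    horizon_years: 3.0
    cycle_length_days: 42.0
    sequence: [lurasidone_adolescent, haloperidol, aripiprazole, paliperidone, clozapine]
    comparator_sequence: [haloperidol, lurasidone_adolescent, aripiprazole, paliperidone, clozapine]
    no_treatment_relapse: 0.071
    smr: 2.6
    costs: *adolescent_costs
  adult:
    start_age: 18.0               # entry age not prescribed; default adult entry
    horizon_years: 5.0
    cycle_length_days: 42.0
    sequence: [lurasidone_adult, cariprazine, brexpiprazole, clozapine]
    comparator_sequence: [cariprazine, brexpiprazole, lurasidone_adult, clozapine]
    no_treatment_relapse: 0.071
    smr: 2.6
    costs:
      stable_state_cost: 2000.0
      relapse_state_cost: 27906.0
      ae_weight_gain_cost: 92.0
      ae_eps_cost: 220.0
      switching_cost: 687.0           # unprinted - calibration knob
      monitoring_cost_per_cycle: 9.0  # unprinted - calibration knob
      relapse_drug_daily_cost: 0.05   # unprinted - calibration knob
      discount_rate: 0.0
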