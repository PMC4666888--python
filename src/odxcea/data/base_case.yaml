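# Austrian base case for the two-test adjuvant-chemotherapy decision model.
# Probabilities and utilities are fractions; costs in 2011 euros.
units: fraction

# Joint distribution of the latent risk groups
# (clinicopathologic stratum -> genomic stratum -> proportion).
group_proportions:
  low:          {low: 0.3234, intermediate: 0.1257, high: 0.0808}
  intermediate: {low: 0.0853, intermediate: 0.0359, high: 0.0659}
  high:         {low: 0.0973, intermediate: 0.0614, high: 0.1243}

# Probability of adjuvant chemotherapy.  Tested patients follow by_group;
# untested patients follow the observed per-stratum practice in by_ao.
# Pattern T2 (scenario): intermediate-stratum / genomic-low patients
# receive no chemotherapy.
chemo_provision:
  pattern: T1
  by_ao: {low: 0.0, intermediate: 0.5506, high: 0.5757}
  by_group:
    low:          {low: 0.0,    intermediate: 0.1762, high: 0.6344}
    intermediate: {low: 0.1373, intermediate: 0.3656, high: 0.9861}
    high:         {low: 0.1372, intermediate: 0.3665, high: 0.9973}
  t2_overrides:
    intermediate: {low: 0.0}

# 10-year distant-recurrence risks.
recurrence:
  no_chemo:
    by_ao: {low: 0.0539, intermediate: 0.2036, high: 0.2412}
    by_group:
      low:          {low: 0.0261, intermediate: 0.0384, high: 0.1891}
      intermediate: {low: 0.0424, intermediate: 0.1490, high: 0.4423}
      high:         {low: 0.0424, intermediate: 0.1490, high: 0.4423}
  chemo:
    by_ao: {low: 0.0568, intermediate: 0.0735, high: 0.0768}
    by_group:
      low:          {low: 0.0498, intermediate: 0.0562, high: 0.0858}
      intermediate: {low: 0.0579, intermediate: 0.0818, high: 0.0891}
      high:         {low: 0.0579, intermediate: 0.0818, high: 0.0891}

# Chemotherapy toxicity.  Cause probabilities are conditional on a hospital
# visit; they sum to 0.7273 -- the remaining visits carry no cost and do not
# count as adverse drug events.  Fatal toxicity is drawn independently.
toxicity:
  p_hospital_visit: 0.1704
  cause_probs:
    neutropenia_fever_infections: 0.5356
    pain: 0.0751
    nausea_vomiting_dehydration: 0.0602
    gastrointestinal: 0.0564
  cost_by_cause:
    neutropenia_fever_infections: 5231.46
    pain: 3270.66
    nausea_vomiting_dehydration: 3173.45
    gastrointestinal: 5169.31
  p_fatal: 0.001
  cost_fatal: 36260.0

costs:
  odx_test: 3180.0
  chemo_total: 11372.96
  other_treatment_5y_total: 5016.8
  followup_per_month_first5y: 21.54
  followup_per_month_after5y: 9.79
  recurrence_diagnosis: 248.5
  recurrence_treatment_total: 32015.26
  recurrence_treatment_months: 25.8

utilities:
  first_year_hormone: 0.744
  first_year_chemo: 0.620
  pre_recurrence: 0.779
  post_recurrence: 0.685
  dead: 0.0

economics:
  discount_rate: 0.05
  cohort_age: 50
  n_patients: 100000
  median_survival_recurrence_months: 25.8
  chemo_duration_months: 6.0
  followup_switch_months: 60.0
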