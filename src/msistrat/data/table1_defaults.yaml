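# Canonical model inputs: annual U.S. de novo metastatic colorectal cancer
# cohort, diagnostic assay operating points, and first-line therapy costs
# (all values published 2017-2020, USD; turnarounds in days, durations in
# months). The AI turnaround is a nominal assumed value of 0 days.
population:
  annual_incidence: 147950
  metastatic_fraction: 0.22
  msih_prevalence: 0.05
assays:
  ngs:
    name: ngs
    sensitivity: 1.00
    specificity: 1.00
    cost_per_patient: 3500.00
    turnaround_days: 12
  panel_high_sens:
    name: panel_high_sens
    sensitivity: 1.00
    specificity: 0.81
    cost_per_patient: 1206.25
    turnaround_days: 4
  panel_high_spec:
    name: panel_high_spec
    sensitivity: 0.67
    specificity: 0.93
    cost_per_patient: 1206.25
    turnaround_days: 4
  ai_high_sens:
    name: ai_high_sens
    sensitivity: 0.98
    specificity: 0.79
    cost_per_patient: 6.07
    turnaround_days: 0
  ai_high_spec:
    name: ai_high_spec
    sensitivity: 0.70
    specificity: 0.98
    cost_per_patient: 6.07
    turnaround_days: 0
pembro:
  monthly_cost: 23021.13
  dose_interval_months: 0.69
  doses_before_first_scan: 3
  full_course_months: 24.15   # 35 doses at 0.69-month intervals (trial cap)
  scan_interval_months: 2.07
  fp_discontinuation_doses: 3
  fp_dose_price_basis: monthly_rate_per_dose
chemo:
  components:
    - name: folfox_bevacizumab
      share: 0.35
      monthly_cost: 6316.70
      per_dose_cost: 3158.35
      median_months_on_therapy: 10.3
    - name: folfox_cetuximab
      share: 0.45
      monthly_cost: 11945.73
      per_dose_cost: 5972.86
      median_months_on_therapy: 10.0
    - name: fu_leucovorin
      share: 0.20
      monthly_cost: 179.76
      per_dose_cost: 63.63
      median_months_on_therapy: 4.4
  weighted_monthly_cost: 7625.88
  weighted_median_months: 9.0
  weighted_per_dose_cost: 3807.68
  dose_interval_months: 0.46
  doses_before_first_scan: 5
  fn_cost_policy: tn_only
guideline:
  max_working_days: 10
reporting_scale: billions_2dp
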