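# Base-case configuration: early heart-failure diagnostic imaging,
# Fast-SENC strain-encoded CMR vs resting echocardiography.
# All money in USD; all rates/probabilities annual unless noted.
schema_version: 1
comparator: ECHO
intervention: FastSENC

strategies:
  ECHO:
    name: ECHO
    diagnostic_accuracy: 0.0      # fails to detect asymptomatic (Stage B) HF
    test_cost: 231.0              # Medicare fee schedule, resting echo
    test_reimbursement: 231.0
    contrast_cost: 45.0           # contrast medicine per scan (payer)
    hospitalization_reduction: 0.0
  FastSENC:
    name: FastSENC
    diagnostic_accuracy: 1.0      # rest diagnostic accuracy for early HF
    test_cost: 324.0              # Medicare fee schedule, CMR rest
    test_reimbursement: 324.0
    contrast_cost: 0.0            # no contrast required
    hospitalization_reduction: 0.271   # = 54.2% preventable x 50% captured

transitions:            # annual next-stage progression + HF mortality
  ECHO:     {stage_b_to_c: 0.0427, stage_c_to_cplus: 0.0455, stage_cplus_to_d: 0.0450, hf_mortality: 0.0694}
  FastSENC: {stage_b_to_c: 0.0311, stage_c_to_cplus: 0.0332, stage_cplus_to_d: 0.0328, hf_mortality: 0.0543}

costs:
  office_visit_cost: 165.0            # outpatient/office visits per year
  drug_cost_monthly: 367.0            # standard HF pharmacotherapy, PMPM
  advanced_drug_cost_monthly: 580.0   # advanced HF pharmacotherapy, PMPM
  hf_hospitalization_prob: 0.3202     # annualized HF hospitalization rate
  hf_hospitalization_cost: 23077.0    # mean cost of an HF hospitalization
  rehospitalization_prob_30d: 0.269   # 30-day HF rehospitalization
  intervention_prob: 0.25             # Stage C annual procedural intervention (placeholder)
  intervention_cost: 14989.0          # ischemic heart disease hospitalization
  palliative_cost: 6960.0             # Stage D palliative care /yr (placeholder: advanced-drug level)
  assist_device_prob: 0.20            # Stage D assist-device implantation /yr (placeholder)
  assist_device_cost: 23077.0         # placeholder: hospitalization-cost level

utilities: {StageB: 0.80, StageC: 0.80, StageCplus: 0.65, StageD: 0.30, Dead: 0.0}

discount:
  rate_costs: 0.03
  rate_outcomes: 0.03
  convention: first_cycle_undiscounted

cohort:
  mean_age: 64.0
  max_age: 110.0
  hf_pretest_prevalence: 0.20        # Stage B+ HF after comorbidity screening
  hf_stage_split: [0.50, 0.25, 0.25] # HF fraction split across B / C / C+ at entry
  stageB_4yr_progression: 0.154      # 4-year Stage-B incidence in the suspected group
  background_mortality:              # Gompertz-style approximation, NOT an official life table
    ages:  [60, 65, 70, 75, 80, 85, 90, 95, 100, 105, 110]
    probs: [0.00949, 0.01503, 0.0238, 0.03771, 0.05973, 0.09462, 0.14988, 0.23742, 0.37609, 0.59576, 0.94372]

detection:
  enabled: true
  post_hosp_diagnosis_rate: 0.5      # P(diagnosis | HF hospitalization) for missed patients
  annual_rescreening: true

engine:
  stop_epsilon: 1.0e-9
  max_cycles: 100
  cost_weighting: stay_probability   # per-state costs weighted by (1 - exit probability)
  qaly_mode: state_specific
  half_cycle_correction: false
  apply_background_mortality: true
  stage_b_hf_mortality: true

hospital:                 # one-year purchaser-perspective inputs
  annual_imaged_population: 3000     # high-risk patients imaged per year
  hf_prevalence: 0.20
  followup_scans_per_identified_patient: 2
  hosp_reimbursement: 14631.0        # blended CMS/private HF hospitalization reimbursement
  hosp_cost: 7463.0                  # HF hospitalization cost (NIS 2015)
  rehosp_30d_prob: 0.269
  procedure_rates: {ICD: 0.48, CRT: 0.20, valve: 0.045, ablation: 0.0079, revascularization: 0.047}
  procedure_margins: {}              # per-procedure margins not published; supply to price planned volume
  strategies:
    ECHO:
      test_reimbursement: 231.0
      contrast_reimbursement: 34.0
      facility_cost_per_hour: 200.0
      machine_minutes: 30
      contrast_cost: 34.0
      reading_fee: 50.0
      test_inventory_cost: 0.0
      diagnostic_accuracy: 0.0
    FastSENC:
      test_reimbursement: 324.0
      contrast_reimbursement: 0.0
      facility_cost_per_hour: 320.0
      machine_minutes: 12
      contrast_cost: 0.0
      reading_fee: 0.0
      test_inventory_cost: 150.0
      diagnostic_accuracy: 1.0
      # component sum gives $218.67/visit; the published downstream margins
      # are internally consistent with $209.33 -- both are reported
      per_visit_cost_override: 209.3333333333
      ownership:
        acquisition: 40000.0         # one-time software acquisition
        annual_maintenance: 10000.0
        equipment_lifetime: 10
        amortization_population: 3000

sensitivity:
  wtp: 50000.0            # willingness-to-pay threshold, USD/QALY
  outcome: cost_per_qaly
  ranges:                 # repo defaults: +/-50% around base; [0.8, 1] for accuracy
    - {path: strategies.FastSENC.diagnostic_accuracy, low: 0.8, high: 1.0}
    - {path: detection.post_hosp_diagnosis_rate, low: 0.25, high: 0.75}
    - {path: strategies.FastSENC.hospitalization_reduction, low: 0.1355, high: 0.4065}
    - {path: strategies.FastSENC.test_cost, low: 162.0, high: 486.0}
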