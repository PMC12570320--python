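# Smoking-history cohort: heavy smokers aged 50-74, annual volume-based
# LDCT for 10 rounds.  Round 1 uses the trial's baseline-round outcome
# probabilities; rounds 2+ use its second-round probabilities.

include: [common.yaml]

cohort_label: smoking

scan_tables:
  first:
    regular: {negative: 0.7921, indeterminate: 0.1920, positive: 0.0159}
    recall: {negative: 0.9457, positive: 0.0543}
    negatives: {true_negative: 0.9993, false_negative: 0.0007}
    positives: {true_positive: 0.3867, false_positive: 0.6133}
    stage_distribution: {I: 0.6486, II: 0.0946, III: 0.1892, IV: 0.0676}
  subsequent:
    regular: {negative: 0.9217, indeterminate: 0.0658, positive: 0.0125}
    recall: {negative: 0.9123, positive: 0.0877}
    negatives: {true_negative: 0.9990, false_negative: 0.0010}
    positives: {true_positive: 0.4435, false_positive: 0.5565}
    stage_distribution: {I: 0.7586, II: 0.0690, III: 0.1379, IV: 0.0345}

epidemiology:
  total_population: 7333200
  age_band_fraction: 0.3732          # population aged 50-74
  smoker_fractions: {daily: 0.104, ex: 0.094}
  eligible_current_smokers: 133000
  eligible_ex_smokers: 107910
  nonsmoker_high_risk_fraction: 0.10
  annual_lc_incidence: 3290          # cases/year, ages 50-74
  clinical_stage_distribution: {I: 0.1732, II: 0.0476, III: 0.1461, IV: 0.6331}
  mean_entry_age: 58.0
  uptake: 0.465
  adherence_round2plus: 1.0
  # interval/clinical incidence calibration anchor: expected lifetime lung
  # cancer diagnoses in a no-screening cohort of the given arm size
  target_diagnoses: 18680
  target_arm_size: 112023

econ:
  n_screen_rounds: 10
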