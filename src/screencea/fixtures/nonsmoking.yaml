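# Risk-factor cohort (never/long-quit smokers aged 55-75 with family
# history, passive-smoke or cooking-fume exposure, or chronic lung disease):
# a single LDCT round with a single-pass decision tree (no indeterminate
# branch) that can also detect stage 0 (carcinoma in situ).

include: [common.yaml]

cohort_label: nonsmoking

scan_tables:
  first:
    regular: {negative: 0.8257, indeterminate: 0.0, positive: 0.1743}
    recall: {negative: 1.0, positive: 0.0}    # degenerate: no recall branch
    negatives: {true_negative: 0.9975, false_negative: 0.0025}
    positives: {true_positive: 0.1399, false_positive: 0.8601}
    stage_distribution:
      {"0": 0.1918, I: 0.7736, II: 0.0094, III: 0.0094, IV: 0.0157}
  subsequent:
    regular: {negative: 0.8257, indeterminate: 0.0, positive: 0.1743}
    recall: {negative: 1.0, positive: 0.0}
    negatives: {true_negative: 0.9975, false_negative: 0.0025}
    positives: {true_positive: 0.1399, false_positive: 0.8601}
    stage_distribution:
      {"0": 0.1918, I: 0.7736, II: 0.0094, III: 0.0094, IV: 0.0157}

epidemiology:
  total_population: 7333200
  age_band_fraction: 0.2946          # population aged 55-74
  smoker_fractions: {daily: 0.104, ex: 0.094}
  nonsmoking_pool: 1962185           # not currently smoking, aged 55-74
  nonsmoker_high_risk_fraction: 0.10
  annual_lc_incidence: 3028          # cases/year, ages 55-75
  clinical_stage_distribution: {I: 0.1732, II: 0.0476, III: 0.1461, IV: 0.6331}
  mean_entry_age: 65.0               # midpoint of the 55-75 eligibility band
  uptake: 0.465
  adherence_round2plus: 1.0
  target_diagnoses: 1615
  target_arm_size: 91241

econ:
  n_screen_rounds: 1
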