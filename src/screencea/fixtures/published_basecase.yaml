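# Published base-case arm totals for both cohorts, as printed in the source
# cost-effectiveness study's results table.  Used for incremental/ICER/NMB
# accounting-identity checks and cross-cohort reporting; the incremental
# column is always recomputed from the two arms, never stored.
# Counts are persons; LY/QALY discounted at 3.5%/y; costs USD 2023.

smoking:
  screening:
    diagnoses_by_stage: {I: 8396, II: 1154, III: 2865, IV: 7283}
    diagnoses_total: 19697
    deaths_by_stage: {I: 4320, II: 712, III: 1542, IV: 7176}
    deaths_total: 13750
    ly_by_stage: {I: 63353, II: 7101, III: 28991, IV: 8454}
    ly_lc_free: 1928403
    ly_total: 2036301
    qaly_by_stage: {I: 47671, II: 5390, III: 21250, IV: 6333}
    qaly_lc_free: 1573927
    qaly_total: 1654571
    screening_cost: 248411526
    diagnostic_cost: 99591903
    treatment_cost_by_stage:
      {I: 137643249, II: 20815767, III: 96116327, IV: 34613132}
    treatment_cost: 289188475
    total_cost: 637191905
  no_screening:
    diagnoses_by_stage: {I: 3235, II: 890, III: 2729, IV: 11827}
    diagnoses_total: 18680
    deaths_by_stage: {I: 1664, II: 549, III: 1464, IV: 11653}
    deaths_total: 15330
    ly_by_stage: {I: 24365, II: 5423, III: 27428, IV: 13721}
    ly_lc_free: 1933804
    ly_total: 2004741
    qaly_by_stage: {I: 18333, II: 4115, III: 20102, IV: 10278}
    qaly_lc_free: 1578308
    qaly_total: 1631135
    screening_cost: 0
    diagnostic_cost: 90252611
    treatment_cost_by_stage:
      {I: 52943619, II: 15906221, III: 90956775, IV: 56177574}
    treatment_cost: 215984190
    total_cost: 306236801

nonsmoking:
  screening:
    diagnoses_by_stage: {I: 1904, II: 71, III: 175, IV: 702}
    diagnoses_stage0: 427
    diagnoses_total: 2853
    deaths_by_stage: {I: 984, II: 44, III: 105, IV: 695}
    deaths_total: 1827
    ly_by_stage: {I: 17973, II: 543, III: 2155, IV: 953}
    ly_lc_free: 193008
    ly_total: 214632
    qaly_by_stage: {I: 13651, II: 416, III: 1585, IV: 714}
    qaly_lc_free: 160938
    qaly_total: 177304
    screening_cost: 23159089
    diagnostic_cost: 54148277
    treatment_cost_by_stage:
      {I: 38453537, II: 1573755, III: 7102353, IV: 3893615}
    treatment_cost: 51023261
    total_cost: 128330627
  no_screening:
    diagnoses_by_stage: {I: 280, II: 77, III: 236, IV: 1022}
    diagnoses_total: 1615
    deaths_by_stage: {I: 144, II: 48, III: 142, IV: 1011}
    deaths_total: 1345
    ly_by_stage: {I: 2639, II: 586, III: 2906, IV: 1387}
    ly_lc_free: 193814
    ly_total: 201333
    qaly_by_stage: {I: 2005, II: 450, III: 2138, IV: 1040}
    qaly_lc_free: 161610
    qaly_total: 167241
    screening_cost: 0
    diagnostic_cost: 9029013
    treatment_cost_by_stage:
      {I: 5646932, II: 1700193, III: 9577269, IV: 5669040}
    treatment_cost: 22593434
    total_cost: 31622448
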