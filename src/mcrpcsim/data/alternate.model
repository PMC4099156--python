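schema_version: 1
variant: alternate
castration_monthly_cost: 371.0
castration_coverage: 0.95
bone_monthly_cost: 585.0
bone_coverage: 0.9
otherx_cap: 24
national_cohort: 4000
states:
- name: AA
  primary_monthly_cost: 58.71
  min_cycles: 4
  p_progress: 0.16072039573676566
  p_death: 0.013971202531645568
  is_last_line: false
- name: AAwd
  primary_monthly_cost: 0.0
  min_cycles: 3
  p_progress: 0.36234766897228177
  p_death: 0.04065624728333783
  is_last_line: false
- name: Abiraterone
  primary_monthly_cost: 3448.94
  min_cycles: 8
  p_progress: 0.04919285162825978
  p_death: 0.017223429048138197
  is_last_line: false
- name: Docetaxel
  primary_monthly_cost: 874.87
  min_cycles: 7
  p_progress: 0.4924587269879057
  p_death: 0.03601009266690958
  is_last_line: false
- name: Cabazitaxel
  primary_monthly_cost: 8473.94
  min_cycles: 3
  p_progress: 0.2084581405752623
  p_death: 0.044866145737830876
  is_last_line: false
- name: OtherTx
  primary_monthly_cost: 0.0
  min_cycles: 0
  p_progress: 0.0
  p_death: 0.044866145737830876
  is_last_line: true
  cap_cycles: 24
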