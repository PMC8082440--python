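prescription_gy: 30.0
slack_delta: 0.03
hard_constraints:
- structure: PTV
  kind: max_dose
  bound_gy: 33.0
- structure: patient
  kind: max_dose
  bound_gy: 33.0
objectives:
- priority: 1
  structure: PTV
  kind: mean_underdose_below
  goal_gy: 0.0
  threshold_gy: 30.0
- priority: 2
  structure: heart
  kind: mean_dose
  goal_gy: 10.0
- priority: 3
  structure: lungs
  kind: mean_dose
  goal_gy: 13.5
- priority: 4
  structure: breast_L
  kind: mean_dose
  goal_gy: 2.0
- priority: 5
  structure: breast_R
  kind: mean_dose
  goal_gy: 2.0
- priority: 6
  structure: lungs
  kind: mean_overdose_above
  goal_gy: 1.0
  threshold_gy: 5.0
- priority: 7
  structure: patient
  kind: mean_dose
  goal_gy: 0.0
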