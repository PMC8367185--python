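# Knowledge-driven candidate filter: treat-to-target intensification plus
# renal dosing rules for metformin.
# Each rule lists predicate conditions (all must hold) over the visit's
# clinical fields and derived on_<drug_class> flags, and the action indices
# it forbids (or force-includes) in the named treatment's action space.
# The shipped set covers the two concrete renal-dosing rules; site-specific
# guideline rules can be appended in the same declarative format.
- id: intensify_when_above_glycemic_target
  treatment_type: antiglycemic
  when:
    - {field: hba1c, op: ">=", value: 7.0}
  forbid: [0, 2]
  note: >
    treat-to-target: when HbA1c is at or above the 7% goal, repeating the
    previous prescription unchanged or de-intensifying is not a candidate
    (clinical-inertia guard); the data-driven ranking chooses among the
    remaining escalation options
- id: metformin_no_dose_increase_egfr_lt45
  treatment_type: antiglycemic
  when:
    - {field: egfr, op: "<", value: 45}
    - {field: on_metformin, op: "==", value: true}
  forbid: [1]
  note: do not increase the metformin dose when eGFR < 45 mL/min/1.73m2
- id: metformin_discontinue_egfr_lt30
  treatment_type: antiglycemic
  when:
    - {field: egfr, op: "<", value: 30}
    - {field: on_metformin, op: "==", value: true}
  forbid: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
  note: >
    discontinue metformin when eGFR < 30: every action that retains it
    (no change, titration, adding another agent alongside it) is excluded,
    leaving only the insulin-regimen switches
- id: metformin_no_start_egfr_lt30
  treatment_type: antiglycemic
  when:
    - {field: egfr, op: "<", value: 30}
  forbid: [5]
  note: never start metformin when eGFR < 30
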