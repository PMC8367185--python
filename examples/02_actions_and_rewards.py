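"""The three canonical treatment action spaces and the clinical rewards.

Antiglycemic actions are *changes* relative to the previous prescription
(13 options); antihypertensive and lipid-lowering actions are the drug-class
subsets currently prescribed (16 and 8 options).
"""

from t2dreco.actions import (
    DEFAULT_DAILY_DOSE,
    Prescription,
    PrescriptionItem,
    apply_action,
    enumerate_actions,
    infer_action,
)
from t2dreco.rewards import RewardInputs, reward

for ttype in ("antiglycemic", "antihypertensive", "lipid_lowering"):
    space = enumerate_actions(ttype)
    print(f"{ttype}: {space.arity} actions; e.g. [{space.arity - 1}] "
          f"{space.labels[-1]!r}")

prev = Prescription("antiglycemic",
                    (PrescriptionItem("metformin", daily_dose=1000.0),))
cur = apply_action(prev, 7, "antiglycemic")  # "Adding sulfonylurea"
print(f"\nmetformin -> {sorted(cur.classes())}: "
      f"inferred action = {infer_action(prev, cur, 'antiglycemic')} "
      f"({enumerate_actions('antiglycemic').labels[7]!r})")

# Rewards score the next visit: +1 for reaching the control target, -2 for a
# severe hypoglycemia admission, and -/+4 at the final visit depending on
# whether any complication or death occurred over the 6-year horizon.
cases = [
    ("controlled, uneventful", RewardInputs(next_hba1c=6.5)),
    ("uncontrolled", RewardInputs(next_hba1c=8.2)),
    ("controlled + hypoglycemia", RewardInputs(next_hba1c=6.0, hypo_before_next=1)),
    ("final visit, no complication",
     RewardInputs(next_hba1c=6.5, is_final=1, cx_sign=-1)),
    ("final visit, complication",
     RewardInputs(next_hba1c=8.0, is_final=1, cx_sign=1)),
]
print()
for label, inp in cases:
    print(f"  glycemic reward [{label}]: {reward('antiglycemic', inp):+g}")
# The attainable range is [-7, +5]: the complication term (weight 4)
# dominates hypoglycemia (2), which dominates single-visit control (1).
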