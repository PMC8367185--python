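"""Clinical reward functions for the three treatment types.

Each transition's reward is computed from next-visit outcomes:

* glycemic:       ``a·sgn(7 − HbA1c') − b·Hypo − c·Final·CX``
* blood pressure: ``a·sgn_joint(SBP'<140 ∧ DBP'<90) − c·Final·CX``
* lipid:          ``a·sgn(2.6 − LDL') − c·Final·CX``

where ``sgn(x) = +1`` if ``x > 0`` else ``−1`` (a value exactly at target
counts as uncontrolled, matching the strict "<" control goals), ``Hypo`` is a
0/1 flag for a severe hypoglycemia admission before the next visit, ``Final``
is a 0/1 flag for the patient's last visit, and ``CX ∈ {−1, +1}`` encodes
whether any complication or death occurs over the follow-up horizon.

Default coefficients ``a=1, b=2, c=4`` weight complication avoidance over
hypoglycemia avoidance over single-target control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class RewardInputError(ValueError):
    pass


@dataclass(frozen=True)
class RewardCoefficients:
    a: float = 1.0
    b: float = 2.0
    c: float = 4.0
    hba1c_target: float = 7.0       # percent
    sbp_target: float = 140.0       # mmHg
    dbp_target: float = 90.0        # mmHg
    ldl_target: float = 2.6         # mmol/L

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise RewardInputError("coefficients a, b, c must be positive")


@dataclass(frozen=True)
class RewardInputs:
    next_hba1c: float | None = None
    next_sbp: float | None = None
    next_dbp: float | None = None
    next_ldl: float | None = None
    hypo_before_next: int = 0
    is_final: int = 0
    cx_sign: int = -1

    def __post_init__(self) -> None:
        if self.cx_sign not in (-1, 1):
            raise RewardInputError("cx_sign must be -1 or +1")
        if self.hypo_before_next not in (0, 1) or self.is_final not in (0, 1):
            raise RewardInputError("hypo_before_next and is_final must be 0/1")


def sgn(x: float) -> int:
    """+1 for x > 0, else −1 (zero maps to −1: exactly at target is
    uncontrolled under a strict '<' goal)."""
    if not math.isfinite(x):
        raise RewardInputError(f"sgn of non-finite value {x!r}")
    return 1 if x > 0 else -1


def _require(value, name: str) -> float:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        raise RewardInputError(f"reward requires field {name!r}")
    return float(value)


def reward(
    treatment_type: str,
    inputs: RewardInputs,
    coef: RewardCoefficients = RewardCoefficients(),
) -> float:
    """Per-transition reward for one treatment type."""
    terminal_term = -coef.c * inputs.is_final * inputs.cx_sign
    if treatment_type == "antiglycemic":
        h = _require(inputs.next_hba1c, "next_hba1c")
        return (
            coef.a * sgn(coef.hba1c_target - h)
            - coef.b * inputs.hypo_before_next
            + terminal_term
        )
    if treatment_type == "antihypertensive":
        sbp = _require(inputs.next_sbp, "next_sbp")
        dbp = _require(inputs.next_dbp, "next_dbp")
        controlled = sbp < coef.sbp_target and dbp < coef.dbp_target
        return coef.a * (1 if controlled else -1) + terminal_term
    if treatment_type == "lipid_lowering":
        ldl = _require(inputs.next_ldl, "next_ldl")
        return coef.a * sgn(coef.ldl_target - ldl) + terminal_term
    raise RewardInputError(f"unknown treatment type {treatment_type!r}")
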