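"""Canonical treatment action spaces.

Three action vocabularies are defined, one per treatment type:

* ``antiglycemic`` — 13 *delta* actions describing the change from the
  previous prescription (no change, dose up/down of the three most common
  dose-titrated drugs, adding one oral antidiabetic drug class, or switching
  to an insulin regimen).
* ``antihypertensive`` — 16 *regimen-subset* actions: every subset of the four
  standard drug classes A (ACE inhibitor / ARB), B (beta blocker),
  C (calcium channel blocker), D (diuretic).
* ``lipid_lowering`` — 8 regimen-subset actions over statin / fibrate /
  ezetimibe.

Delta actions are inferred from a pair of consecutive prescriptions;
subset actions depend only on the current prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

TREATMENT_TYPES = ("antiglycemic", "antihypertensive", "lipid_lowering")

# Oral antidiabetic classes, keyed by their "Adding <class>" action index.
OAD_ADD_INDEX = {
    "alpha_glucosidase_inhibitor": 3,
    "dpp4_inhibitor": 4,
    "metformin": 5,
    "sglt2_inhibitor": 6,
    "sulfonylurea": 7,
    "thiazolidinedione": 8,
    "glp1_receptor_agonist": 9,
}
OAD_CLASSES = tuple(sorted(OAD_ADD_INDEX, key=OAD_ADD_INDEX.get))

INSULIN_CLASSES = ("basal_insulin", "prandial_insulin", "premixed_insulin")

# Insulin regimen -> "Using ..." action index.
INSULIN_REGIMENS = {
    frozenset({"basal_insulin"}): 10,
    frozenset({"premixed_insulin"}): 11,
    frozenset({"basal_insulin", "prandial_insulin"}): 12,
}

# Drugs whose dose titration is a first-class action (indices 1 / 2).
DOSE_ACTION_DRUGS = ("metformin", "basal_insulin", "premixed_insulin")

ANTIGLYCEMIC_LABELS = (
    "No prescription change",
    "Increase drug dosage",
    "Decrease drug dosage",
    "Adding alpha-glucosidase inhibitor",
    "Adding dipeptidyl peptidase-4 inhibitor",
    "Adding metformin",
    "Adding sodium glucose cotransporter-2 inhibitor",
    "Adding sulfonylurea",
    "Adding thiazolidinedione",
    "Adding glucagon-like peptide-1 receptor agonist",
    "Using basal insulin",
    "Using premix insulin",
    "Using basal and prandial insulins",
)

ANTIHYPERTENSIVE_CLASSES = ("ace_arb", "beta_blocker", "ccb", "diuretic")
_AHT_SHORT = dict(zip(ANTIHYPERTENSIVE_CLASSES, "ABCD"))
# Printed row order: none, singles, pairs, triples, full set.
ANTIHYPERTENSIVE_SUBSETS = (
    (), ("ace_arb",), ("beta_blocker",), ("ccb",), ("diuretic",),
    ("ace_arb", "beta_blocker"), ("ace_arb", "ccb"), ("ace_arb", "diuretic"),
    ("beta_blocker", "ccb"), ("beta_blocker", "diuretic"), ("ccb", "diuretic"),
    ("ace_arb", "beta_blocker", "ccb"), ("ace_arb", "beta_blocker", "diuretic"),
    ("ace_arb", "ccb", "diuretic"), ("beta_blocker", "ccb", "diuretic"),
    ("ace_arb", "beta_blocker", "ccb", "diuretic"),
)

LIPID_CLASSES = ("statin", "fibrate", "ezetimibe")
LIPID_SUBSETS = (
    (), ("statin",), ("fibrate",), ("ezetimibe",),
    ("statin", "fibrate"), ("statin", "ezetimibe"), ("fibrate", "ezetimibe"),
    ("statin", "fibrate", "ezetimibe"),
)

DEFAULT_DAILY_DOSE = {
    "metformin": 1000.0,
    "sulfonylurea": 40.0,
    "dpp4_inhibitor": 100.0,
    "sglt2_inhibitor": 10.0,
    "alpha_glucosidase_inhibitor": 150.0,
    "thiazolidinedione": 30.0,
    "glp1_receptor_agonist": 1.0,
    "basal_insulin": 20.0,
    "prandial_insulin": 12.0,
    "premixed_insulin": 30.0,
    "ace_arb": 10.0,
    "beta_blocker": 50.0,
    "ccb": 5.0,
    "diuretic": 25.0,
    "statin": 20.0,
    "fibrate": 160.0,
    "ezetimibe": 10.0,
}

# Multiplicative dose steps for the titration actions.
DOSE_INCREASE_FACTOR = 1.25
DOSE_DECREASE_FACTOR = 0.8

VALID_CLASSES = {
    "antiglycemic": set(OAD_CLASSES) | set(INSULIN_CLASSES),
    "antihypertensive": set(ANTIHYPERTENSIVE_CLASSES),
    "lipid_lowering": set(LIPID_CLASSES),
}


class ActionError(ValueError):
    """Base class for action-space errors."""


class UnknownDrugClassError(ActionError):
    pass


class IncoherentActionError(ActionError):
    """The action cannot be applied to this prescription (e.g. adding a
    drug class that is already prescribed)."""


class UninferableActionError(ActionError):
    """The consecutive prescription pair does not map onto any canonical
    action (e.g. an unrecognized insulin combination)."""


@dataclass(frozen=True)
class PrescriptionItem:
    drug_class: str
    drug_name: str = ""
    daily_dose: float = 0.0


@dataclass(frozen=True)
class Prescription:
    """A prescription of one treatment type: a set of drug-class items."""

    treatment_type: str
    items: tuple[PrescriptionItem, ...] = ()

    def __post_init__(self) -> None:
        valid = VALID_CLASSES[self.treatment_type]
        for it in self.items:
            if it.drug_class not in valid:
                raise UnknownDrugClassError(
                    f"unknown {self.treatment_type} drug class {it.drug_class!r}"
                )
            if it.daily_dose < 0:
                raise ActionError(f"negative dose for {it.drug_class}")

    def classes(self) -> frozenset:
        return frozenset(it.drug_class for it in self.items)

    def dose_of(self, drug_class: str) -> float | None:
        for it in self.items:
            if it.drug_class == drug_class:
                return it.daily_dose
        return None

    def oad_classes(self) -> frozenset:
        return self.classes() & set(OAD_CLASSES)

    def insulin_regimen(self) -> frozenset:
        return self.classes() & set(INSULIN_CLASSES)


@dataclass(frozen=True)
class ActionSpace:
    treatment_type: str
    labels: tuple[str, ...]
    semantics: str  # "delta" | "regimen_subset"
    subsets: tuple[tuple[str, ...], ...] | None = None

    @property
    def arity(self) -> int:
        return len(self.labels)


def _subset_labels(subsets, short: Mapping[str, str] | None, empty_label: str):
    labels = []
    for sub in subsets:
        if not sub:
            labels.append(empty_label)
            continue
        names = [short[c] if short else c for c in sub]
        if len(names) == 1:
            labels.append(f"Using {names[0]}")
        elif len(names) == 2:
            labels.append(f"Using {names[0]} and {names[1]}")
        else:
            labels.append("Using " + ", ".join(names[:-1]) + f", and {names[-1]}")
    return tuple(labels)


def enumerate_actions(treatment_type: str) -> ActionSpace:
    """Return the canonical ordered action space for a treatment type."""
    if treatment_type == "antiglycemic":
        return ActionSpace("antiglycemic", ANTIGLYCEMIC_LABELS, "delta")
    if treatment_type == "antihypertensive":
        return ActionSpace(
            "antihypertensive",
            _subset_labels(ANTIHYPERTENSIVE_SUBSETS, _AHT_SHORT, "No drugs"),
            "regimen_subset",
            ANTIHYPERTENSIVE_SUBSETS,
        )
    if treatment_type == "lipid_lowering":
        return ActionSpace(
            "lipid_lowering",
            _subset_labels(LIPID_SUBSETS, None, "No drugs"),
            "regimen_subset",
            LIPID_SUBSETS,
        )
    raise ActionError(f"unknown treatment type {treatment_type!r}")


def _subset_index(space: ActionSpace, classes: frozenset) -> int:
    for i, sub in enumerate(space.subsets):
        if frozenset(sub) == classes:
            return i
    raise UnknownDrugClassError(
        f"class set {sorted(classes)} not in the {space.treatment_type} vocabulary"
    )


def infer_action(prev: Prescription, cur: Prescription, treatment_type: str) -> int:
    """Map a consecutive prescription pair to the canonical action index.

    Delta semantics (antiglycemic) resolve multiple simultaneous changes by
    precedence: insulin-regimen switch > OAD addition > dose change > no
    change; several added OADs resolve to the lowest canonical index; mixed
    dose directions resolve by the largest relative change.
    """
    if prev.treatment_type != treatment_type or cur.treatment_type != treatment_type:
        raise ActionError("prescription treatment type mismatch")
    space = enumerate_actions(treatment_type)
    if space.semantics == "regimen_subset":
        return _subset_index(space, cur.classes())

    # -- delta semantics --------------------------------------------------
    cur_ins, prev_ins = cur.insulin_regimen(), prev.insulin_regimen()
    if cur_ins and cur_ins != prev_ins:
        try:
            return INSULIN_REGIMENS[cur_ins]
        except KeyError:
            raise UninferableActionError(
                f"unrecognized insulin regimen {sorted(cur_ins)}"
            ) from None
    added = cur.oad_classes() - prev.oad_classes()
    if added:
        return min(OAD_ADD_INDEX[c] for c in added)
    changes = []  # (relative change magnitude, signed direction)
    for drug in DOSE_ACTION_DRUGS:
        d0, d1 = prev.dose_of(drug), cur.dose_of(drug)
        if d0 is None or d1 is None or d1 == d0:
            continue
        rel = (d1 - d0) / d0 if d0 > 0 else 1.0
        changes.append((abs(rel), rel))
    if changes:
        _, rel = max(changes)
        return 1 if rel > 0 else 2
    return 0


def _items_for(classes: Iterable[str], ttype: str) -> tuple[PrescriptionItem, ...]:
    return tuple(
        PrescriptionItem(c, daily_dose=DEFAULT_DAILY_DOSE[c]) for c in classes
    )


def apply_action(prev: Prescription, action: int, treatment_type: str) -> Prescription:
    """Apply a canonical action to a prescription, yielding the new one.

    Raises :class:`IncoherentActionError` when the action is a no-op or
    impossible for ``prev`` (adding a class already present, titrating when
    none of the titratable drugs is prescribed, switching to the insulin
    regimen already in use).
    """
    space = enumerate_actions(treatment_type)
    if not 0 <= action < space.arity:
        raise ActionError(f"action {action} out of range for {treatment_type}")
    if space.semantics == "regimen_subset":
        return Prescription(treatment_type, _items_for(space.subsets[action], treatment_type))

    if action == 0:
        return Prescription(prev.treatment_type, prev.items)
    if action in (1, 2):
        factor = DOSE_INCREASE_FACTOR if action == 1 else DOSE_DECREASE_FACTOR
        present = [d for d in DOSE_ACTION_DRUGS if prev.dose_of(d)]
        if not present:
            raise IncoherentActionError(
                "dose titration requires metformin, basal or premixed insulin"
            )
        items = tuple(
            PrescriptionItem(it.drug_class, it.drug_name, round(it.daily_dose * factor, 6))
            if it.drug_class in present
            else it
            for it in prev.items
        )
        return Prescription(prev.treatment_type, items)
    if action in range(3, 10):
        cls = next(c for c, i in OAD_ADD_INDEX.items() if i == action)
        if cls in prev.classes():
            raise IncoherentActionError(f"{cls} already prescribed; 'Adding' is incoherent")
        return Prescription(
            prev.treatment_type,
            prev.items + (PrescriptionItem(cls, daily_dose=DEFAULT_DAILY_DOSE[cls]),),
        )
    # insulin regimen switch: replaces the whole antiglycemic prescription
    regimen = next(r for r, i in INSULIN_REGIMENS.items() if i == action)
    if prev.insulin_regimen() == regimen:
        raise IncoherentActionError("already on this insulin regimen")
    return Prescription(prev.treatment_type, _items_for(sorted(regimen), prev.treatment_type))


def is_coherent(prev: Prescription, action: int, treatment_type: str) -> bool:
    """True iff ``apply_action`` succeeds and round-trips through
    ``infer_action`` to the same index."""
    try:
        cur = apply_action(prev, action, treatment_type)
    except IncoherentActionError:
        return False
    return infer_action(prev, cur, treatment_type) == action


# -- serialization to/from the registry-table cell format --------------------

def prescription_to_str(rx: Prescription) -> str:
    """Serialize as 'class|name|dose;class|name|dose'; '' means no drugs."""
    return ";".join(
        f"{it.drug_class}|{it.drug_name}|{it.daily_dose:g}" for it in rx.items
    )


def prescription_from_str(cell: str | None, treatment_type: str) -> Prescription | None:
    """Parse a registry rx cell. ``None``/NaN means *no prescription record*;
    an empty string means a recorded prescription of no drugs."""
    if cell is None or (isinstance(cell, float)):  # NaN
        return None
    cell = str(cell).strip()
    if cell == "":
        return Prescription(treatment_type)
    items = []
    for part in cell.split(";"):
        bits = part.split("|")
        if len(bits) != 3:
            raise ActionError(f"malformed prescription item {part!r}")
        cls, name, dose = bits
        items.append(PrescriptionItem(cls, name, float(dose)))
    return Prescription(treatment_type, tuple(items))
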