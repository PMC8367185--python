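"""Knowledge-gated treatment recommendation and concordance flags.

The knowledge-driven rule filter restricts the action space to clinically
admissible candidates (e.g. renal dosing rules for metformin); the trained
Q-model then ranks the admissible candidates by expected cumulative reward.
A visit is *model-concordant* when the physician's actual prescription
change maps (at drug-class level) to the model's top-ranked action.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .actions import (
    Prescription,
    UninferableActionError,
    enumerate_actions,
    infer_action,
)

_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
}


class RuleConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Condition:
    field: str
    op: str
    value: object

    def holds(self, visit_row, prev_rx: dict[str, Prescription | None]) -> bool:
        if self.field.startswith("on_"):
            cls = self.field.removeprefix("on_")
            actual = any(
                rx is not None and cls in rx.classes() for rx in prev_rx.values()
            )
            return _OPS[self.op](actual, bool(self.value))
        return _OPS[self.op](visit_row[self.field], self.value)


@dataclass(frozen=True)
class KnowledgeRule:
    rule_id: str
    treatment_type: str
    when: tuple[Condition, ...]
    forbid: tuple[int, ...] = ()
    force: tuple[int, ...] = ()
    note: str = ""

    def matches(self, visit_row, prev_rx) -> bool:
        return all(c.holds(visit_row, prev_rx) for c in self.when)


def load_rules(path=None) -> list[KnowledgeRule]:
    """Load rules from a YAML file; with no path, the packaged default
    renal-dosing rules."""
    if path is None:
        text = resources.files("t2dreco").joinpath("default_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    docs = yaml.safe_load(text) or []
    rules = []
    for doc in docs:
        ttype = doc["treatment_type"]
        arity = enumerate_actions(ttype).arity
        forbid = tuple(doc.get("forbid", ()))
        force = tuple(doc.get("force", ()))
        for i in forbid + force:
            if not 0 <= i < arity:
                raise RuleConfigError(
                    f"rule {doc['id']}: action index {i} out of range for {ttype}"
                )
        rules.append(
            KnowledgeRule(
                doc["id"],
                ttype,
                tuple(Condition(c["field"], c["op"], c["value"]) for c in doc["when"]),
                forbid,
                force,
                doc.get("note", ""),
            )
        )
    return rules


def knowledge_filter(
    visit_row,
    prev_rx: dict[str, Prescription | None],
    treatment_type: str,
    rules: list[KnowledgeRule],
) -> set[int]:
    """Admissible action indices after applying every matching rule."""
    arity = enumerate_actions(treatment_type).arity
    admissible = set(range(arity))
    forbidden, forced = set(), set()
    for rule in rules:
        if rule.treatment_type != treatment_type or not rule.matches(visit_row, prev_rx):
            continue
        forbidden |= set(rule.forbid)
        forced |= set(rule.force)
    clash = forbidden & forced
    if clash:
        raise RuleConfigError(
            f"contradictory rules: indices {sorted(clash)} both forbidden and forced"
        )
    return (admissible - forbidden) | forced


@dataclass(frozen=True)
class Recommendation:
    patient_id: object
    visit_date: object
    treatment_type: str
    ranked: tuple[tuple[int, float, bool], ...]  # (action, Q, admissible)
    top_k: int

    @property
    def top_action(self) -> int:
        return self.ranked[0][0]

    def top(self) -> tuple[tuple[int, float, bool], ...]:
        return self.ranked[: self.top_k]


def recommend(
    visit_row,
    prev_rx: dict[str, Prescription | None],
    model,
    scheme,
    rules: list[KnowledgeRule],
    k: int = 1,
    treatment_type: str | None = None,
) -> Recommendation:
    """Rank admissible actions by Q-value (ties broken by lower index).

    If the rules forbid everything, falls back to action 0 (no change /
    no drugs) with a warning.
    """
    ttype = treatment_type or model.treatment_type
    state = scheme.encode(visit_row, prev_rx)
    q = model.q_values(state)[0]
    admissible = knowledge_filter(visit_row, prev_rx, ttype, rules)
    if not admissible:
        warnings.warn(
            "all actions forbidden by the rule set; falling back to action 0",
            stacklevel=2,
        )
        admissible = {0}
    order = sorted(admissible, key=lambda i: (-q[i], i))
    ranked = tuple((i, float(q[i]), True) for i in order)
    return Recommendation(
        visit_row.get("patient_id"), visit_row.get("visit_date"), ttype, ranked, k
    )


def concordance(
    rec: Recommendation,
    prev: Prescription,
    cur: Prescription,
) -> bool | None:
    """True iff the physician's actual action equals the top-1 recommended
    action at drug-class level; ``None`` marks an uninferable actual action
    (the sample is excluded, not silently nonconcordant)."""
    try:
        actual = infer_action(prev, cur, rec.treatment_type)
    except UninferableActionError:
        return None
    return actual == rec.top_action
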