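"""Synthetic EMR cohort simulator with a dynamic-programming oracle.

The simulator emulates the statistical structure a registry-trained
recommender assumes, not clinical fidelity: sequential outpatient visits 3-6
months apart; biomarkers relaxing as an AR(1) process toward drug-dependent
set-points plus noise; a severity-dependent physician behavior policy (the
confounding-by-indication mechanism); a logistic severe-hypoglycemia risk in
insulin intensity and glycemia; and complication/death hazards that grow with
biomarker excess above target.  Because the dynamics are simple, the exactly
optimal antiglycemic policy is computable by value iteration on the
simulator's own transition and reward model, which provides the recovery
oracle for training tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema as S
from .actions import (
    DEFAULT_DAILY_DOSE,
    INSULIN_REGIMENS,
    OAD_ADD_INDEX,
    OAD_CLASSES,
    Prescription,
    PrescriptionItem,
    apply_action,
    prescription_to_str,
)
from .cohort import RX_MISSING, Cohort
from .rewards import RewardCoefficients, RewardInputs, reward


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions of the synthetic registry.  All rates are annual,
    all biomarker units match the registry schema (HbA1c %, BP mmHg,
    LDL-c mmol/L)."""

    n_patients: int = 2000
    visits_range: tuple[int, int] = (8, 16)
    gap_months_range: tuple[float, float] = (3.1, 5.9)
    gap_outside_prob: float = 0.1   # occasional gaps outside the 3-6m window
    seed: int = 0

    # glycemic dynamics: h' = (1-kappa) h + kappa * setpoint(drugs) + noise
    hba1c_kappa: float = 0.7
    hba1c_noise_sd: float = 0.4
    hba1c_untreated_sp: float = 9.5
    hba1c_floor: float = 5.5
    oad_pulls: dict = field(
        default_factory=lambda: {
            "metformin": 1.6,
            "sulfonylurea": 1.4,
            "glp1_receptor_agonist": 1.5,
            "sglt2_inhibitor": 1.2,
            "dpp4_inhibitor": 1.1,
            "thiazolidinedione": 1.0,
            "alpha_glucosidase_inhibitor": 0.8,
        }
    )
    insulin_pulls: dict = field(
        default_factory=lambda: {
            frozenset(): 0.0,
            frozenset({"basal_insulin"}): 2.6,
            frozenset({"premixed_insulin"}): 3.2,
            frozenset({"basal_insulin", "prandial_insulin"}): 4.0,
        }
    )
    dose_step_pull: float = 0.25    # extra pull per titration level
    dose_level_range: tuple[int, int] = (-2, 2)

    # blood-pressure / lipid dynamics (same AR(1) form)
    sbp_kappa: float = 0.5
    sbp_noise_sd: float = 6.0
    sbp_untreated_sp: float = 150.0
    sbp_class_pull: float = 9.0     # per antihypertensive class
    dbp_ratio: float = 0.55         # dbp set-point tracks sbp
    dbp_offset: float = -5.0
    dbp_noise_sd: float = 4.0
    ldl_kappa: float = 0.5
    ldl_noise_sd: float = 0.25
    ldl_untreated_sp: float = 3.2
    ldl_pulls: dict = field(
        default_factory=lambda: {"statin": 0.9, "fibrate": 0.35, "ezetimibe": 0.45}
    )

    # severe hypoglycemia admission risk: logistic in insulin intensity and
    # the depth of glycemic control
    hypo_intercept: float = -6.0
    hypo_insulin_coef: float = 1.5
    hypo_lowglu_coef: float = 1.2

    # complication/death hazards: annual log-hazard linear in excess above
    # target.  hazard = base * exp(slope_g*(h-7)+ + slope_bp*(sbp-140)+/10
    #                              + slope_l*(ldl-2.6)+)
    event_base_hazards: dict = field(
        default_factory=lambda: {
            "myocardial_infarction": 0.008,
            "heart_failure": 0.008,
            "stroke": 0.008,
            "nephropathy": 0.015,
            "other_microvascular": 0.015,
            "death": 0.010,
        }
    )
    hazard_slope_glycemic: float = 0.30
    hazard_slope_bp: float = 0.15
    hazard_slope_lipid: float = 0.30
    horizon_years: float = 6.0

    # physician behavior policy: severity-dependent action preferences
    behavior_low: dict = field(
        default_factory=lambda: {"no_change": 0.90, "titrate_down": 0.05,
                                 "titrate_up": 0.01, "add_oad": 0.03, "insulin": 0.01}
    )
    behavior_medium: dict = field(
        default_factory=lambda: {"no_change": 0.45, "titrate_down": 0.02,
                                 "titrate_up": 0.20, "add_oad": 0.28, "insulin": 0.05}
    )
    behavior_high: dict = field(
        default_factory=lambda: {"no_change": 0.20, "titrate_down": 0.01,
                                 "titrate_up": 0.15, "add_oad": 0.29, "insulin": 0.35}
    )
    # inter-physician practice variation: probability of a uniformly random
    # coherent action, independent of severity
    behavior_explore: float = 0.10

    # measurement missingness (labs only; the imputation module fills these)
    missing_rate: float = 0.04
    rx_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for sd in (self.hba1c_noise_sd, self.sbp_noise_sd, self.ldl_noise_sd):
            if sd <= 0:
                raise ValueError("noise SDs must be positive")
        if any(h < 0 for h in self.event_base_hazards.values()):
            raise ValueError("hazards must be non-negative")


# -- glycemic drug-state helpers ---------------------------------------------

DOSE_FACTOR = 1.25


def glycemic_config(rx: Prescription, level_range=(-2, 2)) -> tuple:
    """Collapse an antiglycemic prescription to (OAD set, insulin regimen,
    titration level)."""
    oads = rx.oad_classes()
    regimen = rx.insulin_regimen()
    level = 0
    for drug in ("metformin", "basal_insulin", "premixed_insulin"):
        dose = rx.dose_of(drug)
        if dose:
            level = int(round(math.log(dose / DEFAULT_DAILY_DOSE[drug], DOSE_FACTOR)))
            break
    return frozenset(oads), frozenset(regimen), int(np.clip(level, *level_range))


def setpoint(cfg: SimulatorConfig, oads: frozenset, regimen: frozenset, level: int) -> float:
    sp = cfg.hba1c_untreated_sp
    sp -= sum(cfg.oad_pulls[c] for c in oads)
    sp -= cfg.insulin_pulls[regimen]
    if "metformin" in oads or regimen & {"basal_insulin", "premixed_insulin"}:
        sp -= cfg.dose_step_pull * level
    return max(sp, cfg.hba1c_floor)


def insulin_intensity(regimen: frozenset) -> int:
    """0 none; 1 basal or prandial alone; 2 premix or basal+prandial."""
    if not regimen:
        return 0
    if regimen in (frozenset({"basal_insulin"}), frozenset({"prandial_insulin"})):
        return 1
    return 2


def coherent_glycemic_actions(oads: frozenset, regimen: frozenset) -> list[int]:
    acts = [0]
    if "metformin" in oads or regimen & {"basal_insulin", "premixed_insulin"}:
        acts += [1, 2]
    acts += [OAD_ADD_INDEX[c] for c in OAD_CLASSES if c not in oads]
    acts += [i for r, i in INSULIN_REGIMENS.items() if r != regimen]
    return sorted(acts)


def hypo_probability(cfg: SimulatorConfig, regimen: frozenset, next_h: float) -> float:
    return _sigmoid(
        cfg.hypo_intercept
        + cfg.hypo_insulin_coef * insulin_intensity(regimen)
        + cfg.hypo_lowglu_coef * (7.0 - next_h)
    )


def _event_hazard_scale(cfg: SimulatorConfig, h, sbp, ldl) -> float:
    return math.exp(
        cfg.hazard_slope_glycemic * max(h - 7.0, 0.0)
        + cfg.hazard_slope_bp * max(sbp - 140.0, 0.0) / 10.0
        + cfg.hazard_slope_lipid * max(ldl - 2.6, 0.0)
    )


# -- behavior policy ----------------------------------------------------------

def behavior_action(
    rng: np.random.Generator, cfg: SimulatorConfig, h: float, rx: Prescription
) -> int:
    """Severity-dependent physician policy over coherent antiglycemic actions."""
    oads, regimen, _ = glycemic_config(rx, cfg.dose_level_range)
    coherent = set(coherent_glycemic_actions(oads, regimen))
    if rng.random() < cfg.behavior_explore:
        acts = sorted(coherent)
        return int(acts[rng.integers(len(acts))])
    prefs = (
        cfg.behavior_low if h < 7 else cfg.behavior_medium if h < 9 else cfg.behavior_high
    )
    w = np.zeros(13)
    if 0 in coherent:
        w[0] = prefs["no_change"]
    if 1 in coherent:
        w[1] = prefs["titrate_up"]
    if 2 in coherent:
        w[2] = prefs["titrate_down"]
    add_idx = [OAD_ADD_INDEX[c] for c in OAD_CLASSES if OAD_ADD_INDEX[c] in coherent]
    if add_idx:
        add_w = np.array([3.0 if i == OAD_ADD_INDEX["metformin"] else 1.0 for i in add_idx])
        w[add_idx] = prefs["add_oad"] * add_w / add_w.sum()
    ins_pref = {10: 3.0, 11: 1.0, 12: 0.5}
    if regimen == frozenset({"basal_insulin"}):
        ins_pref = {11: 1.0, 12: 2.0}
    elif regimen == frozenset({"premixed_insulin"}):
        ins_pref = {12: 1.0}
    elif regimen == frozenset({"basal_insulin", "prandial_insulin"}):
        ins_pref = {}
    ins_idx = [i for i in ins_pref if i in coherent]
    if ins_idx:
        tot = sum(ins_pref[i] for i in ins_idx)
        for i in ins_idx:
            w[i] = prefs["insulin"] * ins_pref[i] / tot
    if w.sum() == 0:
        w[0] = 1.0
    return int(rng.choice(13, p=w / w.sum()))


# -- patient-level simulation --------------------------------------------------

_ETHNICITY_P = (0.69, 0.15, 0.11, 0.05)
_HX_BASE_P = {
    "hx_hypertension": 0.60,
    "hx_hypercholesterolemia": 0.60,
    "hx_myocardial_infarction": 0.08,
    "hx_heart_failure": 0.06,
    "hx_stroke": 0.07,
    "hx_nephropathy": 0.12,
    "hx_other_microvascular": 0.15,
    "hx_hypoglycemia": 0.05,
}

_HX_OF_EVENT = {
    "myocardial_infarction": "hx_myocardial_infarction",
    "heart_failure": "hx_heart_failure",
    "stroke": "hx_stroke",
    "nephropathy": "hx_nephropathy",
    "other_microvascular": "hx_other_microvascular",
    "hypoglycemia_admission": "hx_hypoglycemia",
}


def _draw_baseline(rng: np.random.Generator) -> dict:
    return {
        "age": float(np.clip(rng.normal(65, 11), 30, 95)),
        "gender_female": int(rng.random() < 0.49),
        "ethnicity": S.ETHNICITY_LEVELS[rng.choice(4, p=_ETHNICITY_P)],
        "smoker": int(rng.random() < 0.10),
        "diabetes_duration": float(np.clip(rng.normal(10, 7), 0.2, 40)),
        "hba1c": float(np.clip(rng.normal(8.2, 1.4), 5.0, 14.0)),
        "sbp": float(np.clip(rng.normal(135, 16), 95, 200)),
        "dbp": float(np.clip(rng.normal(74, 10), 50, 115)),
        "ldl_c": float(np.clip(rng.normal(2.6, 0.8), 0.5, 6.0)),
        "tg": float(np.clip(rng.normal(1.6, 0.8), 0.3, 8.0)),
        "bmi": float(np.clip(rng.normal(27, 5), 15, 55)),
        "egfr": float(np.clip(rng.normal(80, 25), 8, 140)),
        **{k: int(rng.random() < p) for k, p in _HX_BASE_P.items()},
    }


def _draw_gap_months(rng: np.random.Generator, cfg: SimulatorConfig) -> float:
    if rng.random() < cfg.gap_outside_prob:
        return float(rng.uniform(1.0, 2.9) if rng.random() < 0.5 else rng.uniform(6.1, 9.0))
    return float(rng.uniform(*cfg.gap_months_range))


def _step_aht(rng, cfg, sbp, classes: set) -> set:
    if rng.random() < 0.25:
        from .actions import ANTIHYPERTENSIVE_CLASSES

        absent = [c for c in ANTIHYPERTENSIVE_CLASSES if c not in classes]
        if sbp >= 140 and absent:
            classes = classes | {absent[rng.integers(len(absent))]}
        elif sbp < 118 and classes:
            classes = classes - {sorted(classes)[rng.integers(len(classes))]}
    return classes


def _step_lipid(rng, cfg, ldl, classes: set) -> set:
    if rng.random() < 0.25:
        order = ["statin", "ezetimibe", "fibrate"]
        absent = [c for c in order if c not in classes]
        if ldl >= 2.6 and absent:
            classes = classes | {absent[0]}
        elif ldl < 1.6 and classes:
            classes = classes - {sorted(classes)[rng.integers(len(classes))]}
    return classes


def simulate_cohort(
    cfg: SimulatorConfig,
    policy=None,
    collect=None,
    include_truth: bool = False,
):
    """Generate (visit table, outcome table) in the registry schema.

    ``policy(rng, row, rx_in_use) -> action`` overrides the behavior policy
    for antiglycemic actions (used for policy rollouts); ``collect`` receives
    per-transition reward records when given.  With ``include_truth`` a
    third table carries per-visit ground truth (set-point, oracle inputs).
    """
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp("2013-01-01")
    visit_rows, outcome_rows, truth_rows = [], [], []
    coefs = RewardCoefficients()

    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        base = _draw_baseline(rng)
        first_offset = int(rng.integers(0, 365))
        date = start + pd.Timedelta(days=first_offset)
        n_visits = int(rng.integers(cfg.visits_range[0], cfg.visits_range[1] + 1))
        rx_gly = Prescription("antiglycemic")
        aht_classes: set = set()
        lip_classes: set = set()
        h, sbp, dbp, ldl = base["hba1c"], base["sbp"], base["dbp"], base["ldl_c"]
        tg, bmi, egfr = base["tg"], base["bmi"], base["egfr"]
        hx = {k: base[k] for k in S.HISTORY_FLAGS}
        seen_events: set = set()
        alive = True

        for v in range(n_visits):
            if not alive:
                break
            row = {
                S.PATIENT_ID: pid,
                S.VISIT_DATE: date,
                "age": round(base["age"], 1),
                "gender_female": base["gender_female"],
                "ethnicity": base["ethnicity"],
                "smoker": base["smoker"],
                "diabetes_duration": round(base["diabetes_duration"], 1),
                "hba1c": round(h, 2),
                "sbp": round(sbp, 1),
                "dbp": round(dbp, 1),
                "ldl_c": round(ldl, 2),
                "tg": round(tg, 2),
                "bmi": round(bmi, 1),
                "egfr": round(egfr, 1),
                **hx,
            }
            # antiglycemic action (behavior or injected policy)
            def _rx_of(classes, ttype):
                return Prescription(
                    ttype,
                    tuple(PrescriptionItem(c, daily_dose=DEFAULT_DAILY_DOSE[c])
                          for c in sorted(classes)),
                )

            if policy is None:
                a = behavior_action(rng, cfg, h, rx_gly)
            else:
                in_use = {
                    "antiglycemic": rx_gly,
                    "antihypertensive": _rx_of(aht_classes, "antihypertensive"),
                    "lipid_lowering": _rx_of(lip_classes, "lipid_lowering"),
                }
                a = policy(rng, row, in_use)
            rx_gly = apply_action(rx_gly, a, "antiglycemic")
            aht_classes = _step_aht(rng, cfg, sbp, aht_classes)
            lip_classes = _step_lipid(rng, cfg, ldl, lip_classes)
            rx_aht = _rx_of(aht_classes, "antihypertensive")
            rx_lip = _rx_of(lip_classes, "lipid_lowering")
            row["rx_antiglycemic"] = prescription_to_str(rx_gly)
            row["rx_antihypertensive"] = prescription_to_str(rx_aht)
            row["rx_lipid_lowering"] = prescription_to_str(rx_lip)
            # sporadic missingness exercised by the imputation module
            for col in S.IMPUTABLE_FIELDS:
                if rng.random() < cfg.missing_rate:
                    row[col] = np.nan
            for col in S.RX_COLUMNS.values():
                if rng.random() < cfg.rx_missing_rate:
                    row[col] = None
            visit_rows.append(row)

            oads, regimen, level = glycemic_config(rx_gly, cfg.dose_level_range)
            sp = setpoint(cfg, oads, regimen, level)
            if include_truth:
                truth_rows.append(
                    {S.PATIENT_ID: pid, S.VISIT_DATE: date, "action": a,
                     "setpoint": sp, "hba1c_true": h}
                )

            # evolve biomarkers to the next visit
            gap_days = _draw_gap_months(rng, cfg) * S.DAYS_PER_MONTH
            next_date = date + pd.Timedelta(days=round(gap_days))
            years = gap_days / S.DAYS_PER_YEAR
            h_next = float(
                np.clip(
                    (1 - cfg.hba1c_kappa) * h + cfg.hba1c_kappa * sp
                    + rng.normal(0, cfg.hba1c_noise_sd),
                    4.0, 16.0,
                )
            )
            sbp_sp = cfg.sbp_untreated_sp - cfg.sbp_class_pull * len(aht_classes)
            sbp_next = float(
                np.clip((1 - cfg.sbp_kappa) * sbp + cfg.sbp_kappa * sbp_sp
                        + rng.normal(0, cfg.sbp_noise_sd), 85, 220)
            )
            dbp_sp = cfg.dbp_ratio * sbp_next + cfg.dbp_offset
            dbp_next = float(
                np.clip(0.5 * dbp + 0.5 * dbp_sp + rng.normal(0, cfg.dbp_noise_sd),
                        45, 130)
            )
            ldl_sp = max(
                cfg.ldl_untreated_sp - sum(cfg.ldl_pulls[c] for c in lip_classes), 0.8
            )
            ldl_next = float(
                np.clip((1 - cfg.ldl_kappa) * ldl + cfg.ldl_kappa * ldl_sp
                        + rng.normal(0, cfg.ldl_noise_sd), 0.4, 8.0)
            )
            tg = float(np.clip(0.9 * tg + 0.1 * 1.6 + rng.normal(0, 0.15), 0.3, 8.0))
            bmi = float(np.clip(bmi + rng.normal(0, 0.3), 15, 55))
            egfr = float(np.clip(egfr - 1.0 * years + rng.normal(0, 2.0), 5, 140))

            # severe hypoglycemia admission in the interval
            p_hypo = hypo_probability(cfg, regimen, h_next)
            hypo = rng.random() < p_hypo
            if hypo:
                offset = int(rng.integers(1, max(int(gap_days), 2)))
                outcome_rows.append(
                    {S.PATIENT_ID: pid, "event_type": "hypoglycemia_admission",
                     "event_date": date + pd.Timedelta(days=offset)}
                )
                hx = {**hx, "hx_hypoglycemia": 1}
            # complications and death
            scale = _event_hazard_scale(cfg, h_next, sbp_next, ldl_next)
            for ev, lam in cfg.event_base_hazards.items():
                if ev in seen_events:
                    continue
                if rng.random() < 1.0 - math.exp(-lam * scale * years):
                    offset = int(rng.integers(1, max(int(gap_days), 2)))
                    ev_date = date + pd.Timedelta(days=offset)
                    outcome_rows.append(
                        {S.PATIENT_ID: pid, "event_type": ev, "event_date": ev_date}
                    )
                    seen_events.add(ev)
                    if ev == "death":
                        alive = False
                    elif ev in _HX_OF_EVENT:
                        hx = {**hx, _HX_OF_EVENT[ev]: 1}

            if collect is not None:
                r = reward(
                    "antiglycemic",
                    RewardInputs(next_hba1c=h_next, hypo_before_next=int(hypo)),
                    coefs,
                )
                collect.append({"patient_id": pid, "visit": v, "reward": r,
                                "action": a, "hba1c_next": h_next})

            h, sbp, dbp, ldl = h_next, sbp_next, dbp_next, ldl_next
            date = next_date

        # post-follow-up horizon: events after the last visit
        if alive:
            scale = _event_hazard_scale(cfg, h, sbp, ldl)
            for ev, lam in cfg.event_base_hazards.items():
                if ev in seen_events:
                    continue
                if rng.random() < 1.0 - math.exp(-lam * scale * cfg.horizon_years):
                    offset = int(rng.integers(30, int(cfg.horizon_years * 365)))
                    outcome_rows.append(
                        {S.PATIENT_ID: pid, "event_type": ev,
                         "event_date": date + pd.Timedelta(days=offset)}
                    )
                    seen_events.add(ev)

    visits = pd.DataFrame(visit_rows)
    outcomes = pd.DataFrame(
        outcome_rows, columns=[S.PATIENT_ID, "event_type", "event_date"]
    )
    if include_truth:
        return visits, outcomes, pd.DataFrame(truth_rows)
    return visits, outcomes


def as_cohort(visits: pd.DataFrame, outcomes: pd.DataFrame) -> Cohort:
    """Wrap simulator output as a Cohort without a round-trip through disk."""
    return Cohort(visits.copy(), outcomes.copy())


def write_tables(visits: pd.DataFrame, outcomes: pd.DataFrame, visit_path, outcome_path):
    """Serialize to the delimited registry format (missing rx -> sentinel)."""
    out = visits.copy()
    for col in S.RX_COLUMNS.values():
        out[col] = out[col].where(out[col].notna(), RX_MISSING)
    out[S.VISIT_DATE] = pd.to_datetime(out[S.VISIT_DATE]).dt.strftime("%Y-%m-%d")
    out.to_csv(visit_path, index=False)
    oc = outcomes.copy()
    if not oc.empty:
        oc["event_date"] = pd.to_datetime(oc["event_date"]).dt.strftime("%Y-%m-%d")
    oc.to_csv(outcome_path, index=False)


# -- policy rollout value ------------------------------------------------------

def policy_value(cfg: SimulatorConfig, policy=None, n_patients: int | None = None,
                 seed: int | None = None) -> float:
    """Mean per-transition glycemic reward of a policy under the simulator
    (behavior policy when ``policy`` is None)."""
    run_cfg = replace(
        cfg,
        n_patients=n_patients or cfg.n_patients,
        seed=cfg.seed if seed is None else seed,
        missing_rate=0.0,
        rx_missing_rate=0.0,
    )
    records: list = []
    simulate_cohort(run_cfg, policy=policy, collect=records)
    return float(np.mean([r["reward"] for r in records]))


# -- dynamic-programming oracle ------------------------------------------------

@dataclass
class OraclePolicy:
    """Optimal antiglycemic policy for the simulator's own MDP."""

    cfg: SimulatorConfig
    gamma: float
    h_edges: np.ndarray
    h_centers: np.ndarray
    configs: list            # (oads, regimen, level) tuples
    config_index: dict
    policy: np.ndarray       # (n_configs, n_bins) int
    values: np.ndarray       # (n_configs, n_bins)

    def _bin(self, h: float) -> int:
        return int(np.clip(np.searchsorted(self.h_edges, h) - 1, 0,
                           len(self.h_centers) - 1))

    def action_for(self, rx: Prescription, h: float) -> int:
        key = glycemic_config(rx, self.cfg.dose_level_range)
        return int(self.policy[self.config_index[key], self._bin(h)])

    def as_policy_fn(self):
        def fn(rng, row, rx_in_use):
            return self.action_for(rx_in_use["antiglycemic"], row["hba1c"])

        return fn


def _transition_config(key: tuple, action: int, level_range) -> tuple:
    oads, regimen, level = key
    if action == 0:
        return key
    if action == 1:
        return oads, regimen, min(level + 1, level_range[1])
    if action == 2:
        return oads, regimen, max(level - 1, level_range[0])
    if 3 <= action <= 9:
        cls = next(c for c, i in OAD_ADD_INDEX.items() if i == action)
        return frozenset(oads | {cls}), regimen, level
    regimen_new = next(r for r, i in INSULIN_REGIMENS.items() if i == action)
    return frozenset(), regimen_new, 0


def oracle_policy(
    cfg: SimulatorConfig,
    gamma: float = 0.9,
    n_bins: int = 40,
    h_range: tuple[float, float] = (4.0, 16.0),
    tol: float = 1e-6,
    max_iter: int = 5000,
    coef: RewardCoefficients = RewardCoefficients(),
) -> OraclePolicy:
    """Value iteration on the discretized (glycemia x drug-state) MDP.

    States are HbA1c bins crossed with reachable drug configurations;
    transitions use the simulator's AR(1) law; rewards come from the reward
    module (glycemic term plus the expected hypoglycemia penalty; terminal
    complication terms do not enter this infinite-horizon proxy).
    """
    from scipy.stats import norm

    edges = np.linspace(*h_range, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # reachable drug configurations (breadth-first from untreated)
    start = (frozenset(), frozenset(), 0)
    configs, index, frontier = [start], {start: 0}, [start]
    while frontier:
        key = frontier.pop()
        for a in coherent_glycemic_actions(key[0], key[1]):
            nxt = _transition_config(key, a, cfg.dose_level_range)
            if nxt not in index:
                index[nxt] = len(configs)
                configs.append(nxt)
                frontier.append(nxt)

    n_c = len(configs)
    # next-h transition matrix per config (depends only on its set-point)
    sps = np.array([setpoint(cfg, *key) for key in configs])
    T = np.empty((n_c, n_bins, n_bins))
    for ci, sp in enumerate(sps):
        mu = (1 - cfg.hba1c_kappa) * centers + cfg.hba1c_kappa * sp
        z = (edges[None, :] - mu[:, None]) / cfg.hba1c_noise_sd
        cdf = norm.cdf(z)
        P = np.diff(cdf, axis=1)
        P[:, 0] += cdf[:, 0]
        P[:, -1] += 1.0 - cdf[:, -1]
        T[ci] = P

    # expected immediate reward after landing in bin j under config c
    r_land = np.empty((n_c, n_bins))
    for ci, key in enumerate(configs):
        p_h = np.array([hypo_probability(cfg, key[1], h) for h in centers])
        r0 = np.array([
            reward("antiglycemic", RewardInputs(next_hba1c=h), coef) for h in centers
        ])
        r1 = np.array([
            reward("antiglycemic", RewardInputs(next_hba1c=h, hypo_before_next=1), coef)
            for h in centers
        ])
        r_land[ci] = (1 - p_h) * r0 + p_h * r1

    # action -> successor config index; -1 marks incoherent actions
    succ = np.full((n_c, 13), -1, dtype=int)
    for ci, key in enumerate(configs):
        for a in coherent_glycemic_actions(key[0], key[1]):
            succ[ci, a] = index[_transition_config(key, a, cfg.dose_level_range)]

    V = np.zeros((n_c, n_bins))
    R = np.einsum("cij,cj->ci", T, r_land)  # (n_c, n_bins) immediate reward
    for it in range(max_iter):
        EV = np.einsum("cij,cj->ci", T, V)
        Q = np.full((n_c, 13, n_bins), -np.inf)
        for a in range(13):
            ok = succ[:, a] >= 0
            cs = succ[ok, a]
            Q[ok, a, :] = R[cs] + gamma * EV[cs]
        V_new = Q.max(axis=1)
        if np.max(np.abs(V_new - V)) < tol:
            V = V_new
            break
        V = V_new
    else:
        raise RuntimeError(f"value iteration did not converge in {max_iter} sweeps")

    policy = Q.argmax(axis=1)
    return OraclePolicy(cfg, gamma, edges, centers, configs, index, policy, V)


# -- planted-effect generator for the evaluation statistics ------------------

def planted_or_samples(
    n: int,
    true_or: float,
    seed: int = 0,
    confounding: float = 1.0,
    n_covariates: int = 4,
) -> pd.DataFrame:
    """Visit-level samples with a known exposure odds ratio.

    Covariates shift both exposure propensity (strength ``confounding``) and
    outcome risk, so the crude OR is biased while the true conditional OR is
    ``true_or`` — the test bench for the inverse-probability-weighting and
    weighted-regression estimators.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_covariates))
    lin_exp = confounding * X[:, : min(2, n_covariates)].sum(axis=1)
    exposure = rng.random(n) < 1 / (1 + np.exp(-lin_exp))
    lin_out = -0.5 + math.log(true_or) * exposure + 0.7 * X[:, : min(2, n_covariates)].sum(axis=1)
    outcome = rng.random(n) < 1 / (1 + np.exp(-lin_out))
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(n_covariates)])
    df["exposure"] = exposure.astype(int)
    df["outcome"] = outcome.astype(int)
    return df
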