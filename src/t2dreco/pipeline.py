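"""End-to-end orchestration: simulate -> build -> train -> recommend ->
evaluate, with policy-value comparisons against the behavior policy and the
dynamic-programming oracle.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import schema as S
from .actions import enumerate_actions
from .cohort import build_trajectories, impute_missing, split_patients
from .dqn import QModel, TrainConfig, train
from .evaluate import (
    SHORT_TERM_SPECS,
    adjusted_or,
    build_outcome_cohort,
    concordance_rate,
    longterm_curves,
    recommend_cohort,
)
from .featurize import fit_scheme
from .recommend import concordance, knowledge_filter, load_rules
from .simulate import (
    OraclePolicy,
    SimulatorConfig,
    as_cohort,
    coherent_glycemic_actions,
    glycemic_config,
    oracle_policy,
    policy_value,
    simulate_cohort,
)


def dqn_policy_fn(model: QModel, scheme, rules):
    """Rollout policy: Q-greedy over admissible *and* coherent actions."""

    def fn(rng, row, rx_in_use):
        state = scheme.encode(row, rx_in_use)
        q = model.q_values(state)[0]
        rx = rx_in_use["antiglycemic"]
        oads, regimen, _ = glycemic_config(rx)
        candidates = set(coherent_glycemic_actions(oads, regimen))
        candidates &= knowledge_filter(row, rx_in_use, "antiglycemic", rules)
        if not candidates:
            return 0
        return min(candidates, key=lambda i: (-q[i], i))

    return fn


def adherence_policy(model: QModel, scheme, rules, cfg: SimulatorConfig):
    """Behavior policy with patient-level adherence heterogeneity.

    Each patient draws an adherence trait a ~ U(0,1), independent of
    severity; at each visit the physician follows the model's recommendation
    with probability a, else standard severity-dependent behavior.  Because
    the trait is independent of baseline risk, the resulting variation in
    per-patient concordance rates carries a purely protective effect — the
    planted ground truth for the long-term curve analyses.
    """
    from .simulate import behavior_action

    traits: dict = {}
    dqn = dqn_policy_fn(model, scheme, rules)

    def fn(rng, row, rx_in_use):
        pid = row["patient_id"]
        if pid not in traits:
            traits[pid] = rng.random()
        if rng.random() < traits[pid]:
            return dqn(rng, row, rx_in_use)
        return behavior_action(rng, cfg, row["hba1c"], rx_in_use["antiglycemic"])

    return fn


def longterm_slope_experiment(
    model: QModel,
    scheme,
    rules,
    cfg: SimulatorConfig,
    n_cohorts: int = 10,
    n_patients: int = 400,
    seed: int = 0,
) -> list[float]:
    """Simulate cohorts under adherence heterogeneity and fit the long-term
    occurrence-vs-concordance-rate slope in each (one slope per cohort)."""
    from .cohort import impute_missing
    from .evaluate import longterm_curves, recommend_cohort
    from .simulate import as_cohort, simulate_cohort

    slopes = []
    for k in range(n_cohorts):
        # the protective configuration strengthens the control->complication
        # hazard link so the planted effect clears the binned-slope noise
        cfg_k = replace(
            cfg, n_patients=n_patients, seed=seed + 7000 + k,
            missing_rate=0.0, rx_missing_rate=0.0,
            hazard_slope_glycemic=0.6,
            event_base_hazards={e: 2 * h for e, h in cfg.event_base_hazards.items()},
        )
        policy = adherence_policy(model, scheme, rules, cfg_k)
        cohort = impute_missing(as_cohort(*simulate_cohort(cfg_k, policy=policy)))
        recs = recommend_cohort(cohort, model, scheme, rules, model.treatment_type)
        flags = concordance_table(cohort, recs, model.treatment_type)
        rates = flags.groupby("patient_id")["concordant"].mean()
        outcome = patient_outcomes(cohort, cfg.horizon_years)
        joined = pd.DataFrame({"rate": rates}).join(outcome, how="inner").dropna()
        slopes.append(longterm_curves(joined["rate"], joined["outcome"]).slope)
    return slopes


def concordance_table(cohort, recommendations, treatment_type) -> pd.DataFrame:
    """Per-visit concordance flags for every recommended visit."""
    from .actions import Prescription, prescription_from_str

    rx_col = S.RX_COLUMNS[treatment_type]
    rows = []
    for pid in cohort.patients():
        grp = cohort.visits_of(pid)
        grp = grp[grp[rx_col].notna()]
        seq = [row for _, row in grp.iterrows()]
        for i, row in enumerate(seq):
            rec = recommendations.get((pid, row[S.VISIT_DATE]))
            if rec is None:
                continue
            prev = (
                prescription_from_str(seq[i - 1][rx_col], treatment_type)
                if i > 0 else Prescription(treatment_type)
            )
            cur = prescription_from_str(row[rx_col], treatment_type)
            flag = concordance(rec, prev, cur)
            if flag is None:
                continue
            rows.append({"patient_id": pid, "visit_date": row[S.VISIT_DATE],
                         "concordant": int(flag)})
    return pd.DataFrame(rows)


def patient_outcomes(cohort, horizon_years: float = 6.0) -> pd.Series:
    """1 if the patient has any complication or death within the horizon
    after their first visit, else 0."""
    out = {}
    for pid in cohort.patients():
        first = cohort.visits_of(pid)[S.VISIT_DATE].min()
        out[pid] = int(
            cohort.has_event_between(
                pid, first, first + pd.Timedelta(days=horizon_years * S.DAYS_PER_YEAR),
                S.COMPLICATION_TYPES,
            )
        )
    return pd.Series(out, name="outcome")


def run_end_to_end(
    seed: int = 0,
    n_patients: int = 2000,
    n_iterations: int = 10_000,
    sim_config: SimulatorConfig | None = None,
    train_config: TrainConfig | None = None,
    eval_patients: int = 400,
    treatment_type: str = "antiglycemic",
    compute_oracle: bool = True,
    n_train_candidates: int = 1,
    selection_patients: int = 150,
    progress: bool = False,
) -> dict:
    """Full pipeline on one simulated registry; returns the key metrics.

    When ``n_train_candidates`` > 1, several Q-models are trained from
    different initialization/sampling seeds and the deployed one is chosen
    by a validation rollout on an independent simulated cohort — ordinary
    model selection, which guards against an unlucky training run.
    """
    cfg = sim_config or SimulatorConfig()
    cfg = replace(cfg, n_patients=n_patients, seed=seed)
    visits, outcomes = simulate_cohort(cfg)
    cohort = impute_missing(as_cohort(visits, outcomes))
    train_cohort, valid_cohort = split_patients(cohort, 0.8, seed)
    scheme = fit_scheme(train_cohort)
    ts = build_trajectories(train_cohort, treatment_type, scheme)
    tcfg = train_config or TrainConfig(
        n_iterations=n_iterations, seed=seed, lr_final=0.0003
    )
    arity = enumerate_actions(treatment_type).arity
    rules = load_rules()
    candidates = []
    for k in range(max(n_train_candidates, 1)):
        cand_cfg = replace(tcfg, seed=tcfg.seed + 50 * k)
        cand = train(
            ts.states, ts.actions, ts.rewards, ts.next_states, ts.terminal,
            arity, cand_cfg, treatment_type, scheme.fingerprint(),
            progress=progress,
        )
        candidates.append(cand)
    if len(candidates) > 1:
        # model selection on an independent simulated validation rollout
        scores = [
            policy_value(cfg, dqn_policy_fn(c, scheme, rules),
                         n_patients=selection_patients, seed=seed + 777)
            for c in candidates
        ]
        model = candidates[int(np.argmax(scores))]
    else:
        model = candidates[0]

    recs = recommend_cohort(valid_cohort, model, scheme, rules, treatment_type)
    flags = concordance_table(valid_cohort, recs, treatment_type)
    rate_overall = float(flags["concordant"].mean())
    per_patient = flags.groupby("patient_id")["concordant"].apply(
        lambda s: concordance_rate(s.tolist())
    )

    spec = SHORT_TERM_SPECS["hba1c_control"]
    samples = build_outcome_cohort(valid_cohort, recs, spec)
    crude, ipw = adjusted_or(samples, spec.covariates)

    outcome = patient_outcomes(valid_cohort, cfg.horizon_years)
    joined = pd.DataFrame({"rate": per_patient}).join(outcome, how="inner").dropna()
    curve = longterm_curves(joined["rate"], joined["outcome"])

    result = {
        "n_transitions": len(ts),
        "final_loss": float(np.mean(model.loss_history[-200:])),
        "concordance_rate": rate_overall,
        "incidence_concordant": crude.incidence_exposed,
        "incidence_nonconcordant": crude.incidence_unexposed,
        "crude_or": crude.odds_ratio,
        "adjusted_or": ipw.odds_ratio,
        "adjusted_or_ci": (ipw.ci_low, ipw.ci_high),
        "longterm_slope": curve.slope,
        "model": model,
        "scheme": scheme,
        "valid_cohort": valid_cohort,
        "sim_config": cfg,
    }

    result["behavior_reward"] = policy_value(
        cfg, None, n_patients=eval_patients, seed=seed + 1
    )
    result["dqn_reward"] = policy_value(
        cfg, dqn_policy_fn(model, scheme, rules), n_patients=eval_patients,
        seed=seed + 1,
    )
    if compute_oracle:
        oracle = oracle_policy(cfg, gamma=tcfg.gamma)
        result["oracle_reward"] = policy_value(
            cfg, oracle.as_policy_fn(), n_patients=eval_patients, seed=seed + 1
        )
    return result
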