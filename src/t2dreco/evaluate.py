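"""Retrospective evaluation of model concordance.

Short-term: patient visits are split into model-concordant and
model-nonconcordant groups; goal-achieving rates after 3-6 months of therapy
are compared by chi-square test, then adjusted by propensity-score inverse
probability weighting and weighted multivariate logistic regression (robust
sandwich variances), optionally within strata of the dominant confounder.

Long-term: per-patient concordance rates (concordant visits / total visits)
are related to complication/death occurrence via binned occurrence curves
with fitted slopes and a multivariate logistic regression that adjusts for a
machine-learned baseline risk score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from . import schema as S
from .cohort import IMPUTED_COL, Cohort
from .actions import Prescription, prescription_from_str
from .recommend import Recommendation, concordance, recommend


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeSpec:
    """A short- or long-term outcome definition.

    Short-term success predicates are strict '<' comparisons on next-visit
    values; the hypoglycemia outcome counts severe admissions within the
    follow-up horizon.  Long-term outcomes are first occurrences of an event
    type within the horizon.
    """

    name: str
    kind: str  # "short_term" | "long_term"
    treatment_type: str
    lab_fields: tuple[str, ...] = ()
    thresholds: tuple[float, ...] = ()
    event_type: str | None = None
    horizon_months: float = 6.0
    covariates: tuple[str, ...] = ()


DEFAULT_COVARIATES = (
    "age", "gender_female", "ethnicity", "smoker", "diabetes_duration",
    "hba1c", "sbp", "dbp", "ldl_c", "tg", "bmi", "egfr",
) + S.HISTORY_FLAGS

SHORT_TERM_SPECS = {
    "hba1c_control": OutcomeSpec(
        "hba1c_control", "short_term", "antiglycemic",
        ("hba1c",), (7.0,), covariates=DEFAULT_COVARIATES,
    ),
    "bp_control": OutcomeSpec(
        "bp_control", "short_term", "antihypertensive",
        ("sbp", "dbp"), (140.0, 90.0), covariates=DEFAULT_COVARIATES,
    ),
    "ldl_control": OutcomeSpec(
        "ldl_control", "short_term", "lipid_lowering",
        ("ldl_c",), (2.6,), covariates=DEFAULT_COVARIATES,
    ),
    "hypoglycemia": OutcomeSpec(
        "hypoglycemia", "short_term", "antiglycemic",
        event_type="hypoglycemia_admission", horizon_months=6.0,
        covariates=DEFAULT_COVARIATES,
    ),
}


def recommend_cohort(cohort: Cohort, model, scheme, rules, treatment_type: str,
                     followup_window=(3.0, 6.0)) -> dict:
    """Top-k recommendations for every eligible visit, keyed by
    (patient_id, visit_date)."""
    rx_col = S.RX_COLUMNS[treatment_type]
    out = {}
    for pid in cohort.patients():
        grp = cohort.visits_of(pid)
        grp = grp[grp[rx_col].notna()]
        rows = [row for _, row in grp.iterrows()]
        for i, row in enumerate(rows):
            prev_rx = {
                t: (prescription_from_str(rows[i - 1][c], t) if i > 0 else Prescription(t))
                for t, c in S.RX_COLUMNS.items()
            }
            rec = recommend(row, prev_rx, model, scheme, rules,
                            treatment_type=treatment_type)
            out[(pid, row[S.VISIT_DATE])] = rec
    return out


def _was_imputed(row, fld: str) -> bool:
    marks = str(row.get(IMPUTED_COL, "") or "")
    return f"{fld}:" in marks


def build_outcome_cohort(
    cohort: Cohort,
    recommendations: dict,
    spec: OutcomeSpec,
    followup_window=(3.0, 6.0),
) -> pd.DataFrame:
    """Visit-level samples with exposure (concordant flag), outcome and
    covariates, applying the outcome-specific exclusions."""
    lo = followup_window[0] * S.DAYS_PER_MONTH
    hi = followup_window[1] * S.DAYS_PER_MONTH
    rx_col = S.RX_COLUMNS[spec.treatment_type]
    samples = []
    for pid in cohort.patients():
        grp = cohort.visits_of(pid)
        death = cohort.death_date(pid)
        if death is not None:
            grp = grp[grp[S.VISIT_DATE] <= death]
        grp = grp[grp[rx_col].notna()]
        if spec.kind == "long_term" and spec.event_type:
            first = cohort.first_event_date(pid, [spec.event_type])
            if first is not None:
                grp = grp[grp[S.VISIT_DATE] <= first]
        rows = [row for _, row in grp.iterrows()]
        for i, row in enumerate(rows):
            rec = recommendations.get((pid, row[S.VISIT_DATE]))
            if rec is None:
                continue
            prev = (
                prescription_from_str(rows[i - 1][rx_col], spec.treatment_type)
                if i > 0 else Prescription(spec.treatment_type)
            )
            cur = prescription_from_str(row[rx_col], spec.treatment_type)
            flag = concordance(rec, prev, cur)
            if flag is None:
                continue
            if spec.event_type is not None:
                horizon = pd.Timedelta(days=spec.horizon_months * S.DAYS_PER_MONTH)
                outcome = int(
                    cohort.has_event_between(
                        pid, row[S.VISIT_DATE], row[S.VISIT_DATE] + horizon,
                        [spec.event_type],
                    )
                )
            else:
                # needs an observed follow-up lab 3-6 months later
                if i + 1 >= len(rows):
                    continue
                nxt = rows[i + 1]
                gap = (nxt[S.VISIT_DATE] - row[S.VISIT_DATE]).days
                if not lo <= gap <= hi:
                    continue
                if any(
                    pd.isna(nxt[f]) or _was_imputed(nxt, f) for f in spec.lab_fields
                ):
                    continue  # no short-term outcome information
                outcome = int(
                    all(nxt[f] < th for f, th in zip(spec.lab_fields, spec.thresholds))
                )
            rec_row = {"patient_id": pid, "exposure": int(flag), "outcome": outcome}
            for cov in spec.covariates:
                rec_row[cov] = row[cov]
            samples.append(rec_row)
    df = pd.DataFrame(samples)
    if df.empty or df["exposure"].nunique() < 2:
        raise EvaluationError(
            f"outcome {spec.name!r}: a concordance group is empty"
        )
    return df


@dataclass
class ComparisonResult:
    n_exposed: int
    n_unexposed: int
    events_exposed: int
    events_unexposed: int
    incidence_exposed: float
    incidence_unexposed: float
    chi2: float
    p_value: float
    odds_ratio: float


def short_term_compare(samples: pd.DataFrame) -> ComparisonResult:
    """2x2 comparison of outcome incidence between concordance groups."""
    e = samples[samples["exposure"] == 1]["outcome"]
    u = samples[samples["exposure"] == 0]["outcome"]
    if len(e) == 0 or len(u) == 0:
        raise EvaluationError("both concordance groups must be non-empty")
    return compare_counts(len(e), int(e.sum()), len(u), int(u.sum()))


def compare_counts(n_exp: int, ev_exp: int, n_unexp: int, ev_unexp: int) -> ComparisonResult:
    """Comparison statistics from the four 2x2 counts directly."""
    a, b = ev_exp, n_exp - ev_exp
    c, d = ev_unexp, n_unexp - ev_unexp
    table = np.array([[a, b], [c, d]], float)
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))  # Haldane-Anscombe
    or_ = (a / b) / (c / d)
    if (table == 0).any():
        chi2, p = chi2_contingency(table + 0.5)[:2]
    else:
        chi2, p = chi2_contingency(table, correction=False)[:2]
    return ComparisonResult(
        n_exp, n_unexp, ev_exp, ev_unexp,
        ev_exp / n_exp, ev_unexp / n_unexp, float(chi2), float(p), float(or_),
    )


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    X = df[list(covariates)].copy()
    obj_cols = [c for c in X.columns if X[c].dtype == object]
    if obj_cols:
        X = pd.get_dummies(X, columns=obj_cols, drop_first=True)
    return X.astype(float)


def propensity_weights(
    samples: pd.DataFrame,
    covariates,
    truncate_pct: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Inverse-probability-of-exposure weights from a main-effects logistic
    propensity model, truncated at the given weight percentiles."""
    X = sm.add_constant(_design(samples, covariates))
    y = samples["exposure"].to_numpy(float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    if not res.converged:
        raise EvaluationError("propensity model did not converge")
    ps = np.clip(res.fittedvalues.to_numpy(), 1e-6, 1 - 1e-6)
    w = np.where(y == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    lo, hi = np.percentile(w, truncate_pct)
    return np.clip(w, lo, hi)


@dataclass
class AdjustedOR:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float
    std_error: float


def weighted_logistic_or(
    samples: pd.DataFrame, weights: np.ndarray, covariates=()
) -> AdjustedOR:
    """Weighted logistic regression of outcome on exposure (+ covariates);
    the exposure coefficient is reported as an OR with robust (sandwich) CIs."""
    if np.any(np.asarray(weights) <= 0):
        raise EvaluationError("weights must be positive")
    cols = ["exposure"] + list(covariates)
    X = sm.add_constant(_design(samples, cols))
    y = samples["outcome"].to_numpy(float)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=np.asarray(weights))
    try:
        res = model.fit(maxiter=200, cov_type="HC0")
    except Exception as err:  # pragma: no cover - separation surfacing
        raise EvaluationError(
            f"weighted logistic fit failed ({err}); consider penalization"
        ) from err
    beta = float(res.params["exposure"])
    se = float(res.bse["exposure"])
    return AdjustedOR(
        math.exp(beta), math.exp(beta - 1.959964 * se), math.exp(beta + 1.959964 * se),
        float(res.pvalues["exposure"]), beta, se,
    )


def adjusted_or(samples: pd.DataFrame, covariates,
                truncate_pct=(1.0, 99.0)) -> tuple[ComparisonResult, AdjustedOR]:
    """Convenience pipeline: crude comparison, then IPW + weighted logistic."""
    crude = short_term_compare(samples)
    w = propensity_weights(samples, covariates, truncate_pct)
    return crude, weighted_logistic_or(samples, w, covariates)


HBA1C_BANDS = ((-np.inf, 7.0, "low"), (7.0, 9.0, "medium"), (9.0, np.inf, "high"))


def stratified_analysis(
    samples: pd.DataFrame,
    covariates,
    stratifier: str = "hba1c",
    bands=HBA1C_BANDS,
) -> dict:
    """Run the compare/weight/regress pipeline within each stratifier band
    (default: current HbA1c low <7 / medium [7,9) / high >=9).  Bands with an
    empty concordance group are reported as absent (None)."""
    out = {}
    covs = [c for c in covariates if c != stratifier]
    for lo, hi, name in bands:
        sub = samples[(samples[stratifier] >= lo) & (samples[stratifier] < hi)]
        if sub.empty or sub["exposure"].nunique() < 2 or sub["outcome"].nunique() < 2:
            out[name] = None
            continue
        out[name] = adjusted_or(sub, covs)
    return out


def concordance_rate(flags) -> float:
    """Concordant visits divided by total visits for one patient."""
    flags = [f for f in flags if f is not None]
    if len(flags) == 0:
        raise EvaluationError("concordance rate needs at least one visit")
    return float(np.mean([bool(f) for f in flags]))


@dataclass
class CurveFit:
    bin_centers: np.ndarray
    occurrence: np.ndarray
    counts: np.ndarray
    slope: float
    intercept: float


def longterm_curves(rates, outcomes, bin_width: float = 0.2) -> CurveFit:
    """Occurrence rate of the outcome per concordance-rate bin, with an OLS
    slope over the non-empty bin points."""
    rates = np.asarray(rates, float)
    outcomes = np.asarray(outcomes, float)
    if np.any((rates < 0) | (rates > 1)):
        raise EvaluationError("concordance rates must lie in [0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(rates, edges) - 1, 0, len(edges) - 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), int)
    for b in range(len(centers)):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            occ[b] = outcomes[mask].mean()
    good = ~np.isnan(occ)
    if good.sum() < 2:
        raise EvaluationError("slope undefined: fewer than 2 non-empty bins")
    slope, intercept = np.polyfit(centers[good], occ[good], 1)
    return CurveFit(centers, occ, counts, float(slope), float(intercept))


def longterm_regression(samples: pd.DataFrame, outcome_col: str = "outcome") -> pd.DataFrame:
    """Logistic regression of a long-term outcome on the three per-patient
    concordance rates plus the baseline risk score.

    ``samples`` must contain rate_antiglycemic / rate_antihypertensive /
    rate_lipid_lowering, risk_score and the outcome; patients missing any
    rate are excluded.
    """
    terms = ["rate_antiglycemic", "rate_antihypertensive", "rate_lipid_lowering",
             "risk_score"]
    df = samples.dropna(subset=terms + [outcome_col])
    X = sm.add_constant(df[terms].astype(float))
    y = df[outcome_col].to_numpy(float)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:
        raise EvaluationError(f"long-term regression failed ({err})") from err
    return pd.DataFrame(
        {"coefficient": res.params, "std_error": res.bse, "p_value": res.pvalues}
    ).loc[terms]


def risk_score_model(
    features: pd.DataFrame,
    outcome,
    method: str = "xgboost",
    n_splits: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Baseline risk scores as held-out probabilities from a gradient-boosted
    classifier (penalized logistic fallback)."""
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    y = np.asarray(outcome, int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("degenerate outcome: only one class present")
    X = _design(features, features.columns)
    if method == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=150, max_depth=3, learning_rate=0.1,
            subsample=0.9, random_state=seed, verbosity=0,
            eval_metric="logloss", n_jobs=1,
        )
    elif method == "logistic":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        clf = make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=1000))
    else:
        raise EvaluationError(f"unknown risk model method {method!r}")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    probs = cross_val_predict(clf, X.to_numpy(), y, cv=cv, method="predict_proba")
    return probs[:, 1]


def standardized_mean_differences(
    samples: pd.DataFrame, covariates, weights=None
) -> pd.Series:
    """Absolute standardized mean differences of covariates between exposure
    groups (weighted when weights are given) — the IPW balance diagnostic."""
    X = _design(samples, covariates)
    e = samples["exposure"].to_numpy() == 1
    w = np.ones(len(samples)) if weights is None else np.asarray(weights, float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(float)
        m1 = np.average(x[e], weights=w[e])
        m0 = np.average(x[~e], weights=w[~e])
        v1 = np.average((x[e] - m1) ** 2, weights=w[e])
        v0 = np.average((x[~e] - m0) ** 2, weights=w[~e])
        pooled = math.sqrt((v1 + v0) / 2)
        out[col] = abs(m1 - m0) / pooled if pooled > 0 else 0.0
    return pd.Series(out)


def medication_pattern_histogram(visits: pd.DataFrame, bands=HBA1C_BANDS) -> pd.DataFrame:
    """Per-HbA1c-band 2D histogram of antiglycemic patterns: x = number of
    distinct OAD classes, y = insulin intensity (0 none; 1 basal or prandial
    alone; 2 premix or basal+prandial combinations)."""
    from .simulate import insulin_intensity

    rows = []
    for _, row in visits.iterrows():
        rx = prescription_from_str(row[S.RX_COLUMNS["antiglycemic"]], "antiglycemic")
        if rx is None or pd.isna(row["hba1c"]):
            continue
        band = next(
            name for lo, hi, name in bands if lo <= row["hba1c"] < hi
        )
        rows.append(
            {"band": band, "n_oads": len(rx.oad_classes()),
             "insulin_intensity": insulin_intensity(rx.insulin_regimen())}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["band", "n_oads", "insulin_intensity", "count"])
    return (
        df.value_counts(["band", "n_oads", "insulin_intensity"])
        .rename("count").reset_index().sort_values(["band", "n_oads", "insulin_intensity"])
        .reset_index(drop=True)
    )
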