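"""Registry loading, missing-data handling and trajectory construction.

A cohort is a pair of tables: visits (one row per outpatient visit) and
outcomes (one row per dated event).  Malformed numeric cells are treated as
missing at load time; missing labs and physical measurements are imputed by
last observation carried forward within a look-back window, falling back to
the population median.  Imputed visits are turned into reinforcement-learning
transitions by pairing consecutive visits whose spacing falls inside the
follow-up window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema as S
from .actions import (
    Prescription,
    UninferableActionError,
    infer_action,
    prescription_from_str,
)
from .rewards import RewardCoefficients, RewardInputs, reward

RX_MISSING = "NA"  # cell sentinel: no prescription record at this visit


class SchemaError(ValueError):
    pass


class DuplicateVisitError(ValueError):
    pass


class DateParseError(ValueError):
    pass


class MissingFieldError(ValueError):
    pass


@dataclass
class Cohort:
    """Visit and outcome tables with per-patient ordering guarantees."""

    visits: pd.DataFrame
    outcomes: pd.DataFrame
    _events: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.visits = self.visits.sort_values([S.PATIENT_ID, S.VISIT_DATE]).reset_index(
            drop=True
        )
        dup = self.visits.duplicated([S.PATIENT_ID, S.VISIT_DATE])
        if dup.any():
            rows = self.visits.loc[dup, [S.PATIENT_ID, S.VISIT_DATE]]
            raise DuplicateVisitError(
                f"duplicate (patient, visit_date) rows: {rows.values.tolist()[:5]}"
            )
        deaths = self.outcomes[self.outcomes["event_type"] == "death"]
        if deaths[S.PATIENT_ID].duplicated().any():
            raise SchemaError("more than one death event for a patient")
        self._events = {
            pid: grp.sort_values("event_date")
            for pid, grp in self.outcomes.groupby(S.PATIENT_ID)
        }

    def patients(self) -> list:
        return sorted(self.visits[S.PATIENT_ID].unique().tolist())

    def visits_of(self, patient_id) -> pd.DataFrame:
        return self.visits[self.visits[S.PATIENT_ID] == patient_id]

    def events_of(self, patient_id, types: Iterable[str] | None = None) -> pd.DataFrame:
        ev = self._events.get(patient_id)
        if ev is None:
            return self.outcomes.iloc[0:0]
        if types is not None:
            ev = ev[ev["event_type"].isin(list(types))]
        return ev

    def first_event_date(self, patient_id, types: Iterable[str]):
        ev = self.events_of(patient_id, types)
        return None if ev.empty else ev["event_date"].min()

    def death_date(self, patient_id):
        return self.first_event_date(patient_id, ["death"])

    def has_event_between(self, patient_id, t0, t1, types: Iterable[str]) -> bool:
        """Any event of the given types with date in (t0, t1]."""
        ev = self.events_of(patient_id, types)
        if ev.empty:
            return False
        d = ev["event_date"]
        return bool(((d > t0) & (d <= t1)).any())

    def subset(self, patient_ids: Iterable) -> "Cohort":
        ids = set(patient_ids)
        return Cohort(
            self.visits[self.visits[S.PATIENT_ID].isin(ids)].copy(),
            self.outcomes[self.outcomes[S.PATIENT_ID].isin(ids)].copy(),
        )


def _parse_dates(series: pd.Series, table: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="mixed")
    bad = parsed.isna() & series.notna()
    if bad.any():
        raise DateParseError(
            f"unparseable dates in {table} at rows {list(series.index[bad][:10])}"
        )
    if parsed.isna().any():
        raise DateParseError(f"missing dates in {table}")
    return parsed


def load_registry(
    visit_table,
    outcome_table,
    schema: Mapping[str, str] | None = None,
) -> Cohort:
    """Load the two delimited registry tables into a :class:`Cohort`.

    ``schema`` optionally maps external column names onto the canonical
    ones.  Malformed numeric cells (and non-positive values of fields that
    must be positive) are recorded as missing and the row is retained.
    """
    visits = pd.read_csv(visit_table, dtype=str, keep_default_na=False)
    outcomes = pd.read_csv(outcome_table, dtype=str, keep_default_na=False)
    if schema:
        visits = visits.rename(columns=dict(schema))
        outcomes = outcomes.rename(columns=dict(schema))

    missing_cols = set(S.VISIT_COLUMNS) - set(visits.columns)
    if missing_cols:
        raise SchemaError(f"visit table lacks mandatory columns {sorted(missing_cols)}")
    if set(S.OUTCOME_COLUMNS) - set(outcomes.columns):
        raise SchemaError("outcome table lacks mandatory columns")

    visits = visits.copy()
    visits[S.VISIT_DATE] = _parse_dates(
        visits[S.VISIT_DATE].replace("", None), "visit table"
    )
    for col in S.CONTINUOUS_FIELDS:
        visits[col] = pd.to_numeric(visits[col], errors="coerce")
        if col in S.POSITIVE_FIELDS:
            visits.loc[visits[col] <= 0, col] = np.nan
    for col in S.BINARY_FIELDS + S.HISTORY_FLAGS:
        visits[col] = (
            visits[col].str.strip().str.lower().isin(["1", "true", "yes"]).astype(int)
        )
    for col in S.RX_COLUMNS.values():
        visits[col] = visits[col].where(visits[col] != RX_MISSING, None)

    bad_types = set(outcomes["event_type"]) - set(S.EVENT_TYPES)
    if bad_types:
        raise SchemaError(f"unknown outcome event types {sorted(bad_types)}")
    outcomes = outcomes.copy()
    outcomes["event_date"] = _parse_dates(
        outcomes["event_date"].replace("", None), "outcome table"
    )
    return Cohort(visits, outcomes)


IMPUTED_COL = "imputed_fields"


def impute_missing(cohort: Cohort, lookback_days: float = S.DAYS_PER_YEAR) -> Cohort:
    """Fill missing labs/measurements by LOCF within ``lookback_days``, then
    by the population median; record per-row imputation sources.

    Idempotent: a fully-imputed cohort passes through unchanged.
    """
    visits = cohort.visits.copy()
    if IMPUTED_COL not in visits.columns:
        visits[IMPUTED_COL] = ""
    sources = visits[IMPUTED_COL].str.split(";").apply(
        lambda xs: [x for x in xs if x] if isinstance(xs, list) else []
    )

    medians = {}
    for col in S.IMPUTABLE_FIELDS:
        observed = visits[col].dropna()
        if observed.empty:
            raise MissingFieldError(f"field {col!r} missing for every visit")
        medians[col] = float(observed.median())

    for col in S.IMPUTABLE_FIELDS:
        if not visits[col].isna().any():
            continue
        for pid, grp in visits.groupby(S.PATIENT_ID, sort=False):
            vals = grp[col]
            if not vals.isna().any():
                continue
            dates = grp[S.VISIT_DATE]
            last_val, last_date = None, None
            for idx in grp.index:
                v = vals.loc[idx]
                if not np.isnan(v):
                    last_val, last_date = v, dates.loc[idx]
                    continue
                if (
                    last_val is not None
                    and (dates.loc[idx] - last_date).days <= lookback_days
                ):
                    visits.at[idx, col] = last_val
                    sources.at[idx] = sources.at[idx] + [f"{col}:locf"]
                else:
                    visits.at[idx, col] = medians[col]
                    sources.at[idx] = sources.at[idx] + [f"{col}:median"]
    visits[IMPUTED_COL] = sources.apply(";".join)
    return Cohort(visits, cohort.outcomes.copy())


def split_patients(cohort: Cohort, ratio: float = 0.8, seed: int = 0):
    """Patient-level train/validation split, deterministic given the seed."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = cohort.patients()
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = [ids[i] for i in perm[:n_train]]
    valid_ids = [ids[i] for i in perm[n_train:]]
    return cohort.subset(train_ids), cohort.subset(valid_ids)


@dataclass
class TransitionSet:
    """Columnar container of RL transitions for one treatment type."""

    treatment_type: str
    states: np.ndarray          # (N, D)
    actions: np.ndarray         # (N,) int
    rewards: np.ndarray         # (N,) float
    next_states: np.ndarray     # (N, D); NaN rows where terminal
    terminal: np.ndarray        # (N,) bool
    patient_ids: np.ndarray
    visit_dates: np.ndarray

    def __len__(self) -> int:
        return len(self.actions)

    def to_frame(self) -> pd.DataFrame:
        d = self.states.shape[1]
        df = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "visit_date": self.visit_dates,
                "action": self.actions,
                "reward": self.rewards,
                "terminal": self.terminal.astype(int),
            }
        )
        for j in range(d):
            df[f"s{j}"] = self.states[:, j]
        for j in range(d):
            df[f"ns{j}"] = self.next_states[:, j]
        return df


def _visit_prescriptions(row) -> dict:
    out = {}
    for ttype, col in S.RX_COLUMNS.items():
        out[ttype] = prescription_from_str(row[col], ttype)
    return out


def _all_labs_imputed(row) -> bool:
    marks = set(m.split(":")[0] for m in str(row.get(IMPUTED_COL, "")).split(";") if m)
    return set(S.IMPUTABLE_FIELDS) <= marks


def build_trajectories(
    cohort: Cohort,
    treatment_type: str,
    scheme,
    followup_window: tuple[float, float] = (3.0, 6.0),  # months
    horizon_years: float = 6.0,
    long_term_event: str | None = None,
    coef: RewardCoefficients = RewardCoefficients(),
) -> TransitionSet:
    """Build (state, action, reward, next-state) transitions.

    Exclusion cascade per patient: visits after death are dropped; visits
    lacking the treatment-type prescription record are dropped; visits whose
    state labs were entirely missing pre-imputation are dropped; in long-term
    mode, visits after the first occurrence of ``long_term_event`` are
    dropped.  Consecutive surviving visits spaced within ``followup_window``
    become transitions; the pair ending at the patient's last surviving visit
    is terminal, with the complication term evaluated over ``horizon_years``.
    """
    lo = followup_window[0] * S.DAYS_PER_MONTH
    hi = followup_window[1] * S.DAYS_PER_MONTH
    horizon_days = horizon_years * S.DAYS_PER_YEAR
    rx_col = S.RX_COLUMNS[treatment_type]

    states, actions, rewards_, next_states, terminals, pids, dates = (
        [], [], [], [], [], [], [],
    )
    n_uninferable = 0
    for pid in cohort.patients():
        grp = cohort.visits_of(pid)
        death = cohort.death_date(pid)
        if death is not None:
            grp = grp[grp[S.VISIT_DATE] <= death]
        grp = grp[grp[rx_col].notna()]
        grp = grp[~grp.apply(_all_labs_imputed, axis=1)]
        if long_term_event is not None:
            first = cohort.first_event_date(pid, [long_term_event])
            if first is not None:
                grp = grp[grp[S.VISIT_DATE] <= first]
        rows = [row for _, row in grp.iterrows()]
        if len(rows) < 2:
            continue
        rx_seq = [_visit_prescriptions(r) for r in rows]
        empty = {t: Prescription(t) for t in S.RX_COLUMNS}
        for i in range(len(rows) - 1):
            v, nxt = rows[i], rows[i + 1]
            gap = (nxt[S.VISIT_DATE] - v[S.VISIT_DATE]).days
            if not lo <= gap <= hi:
                continue
            prev_rx = rx_seq[i - 1] if i > 0 else empty
            try:
                a = infer_action(prev_rx[treatment_type], rx_seq[i][treatment_type],
                                 treatment_type)
            except UninferableActionError:
                n_uninferable += 1
                continue
            is_final = i + 1 == len(rows) - 1
            cx = 1 if (
                is_final
                and cohort.has_event_between(
                    pid, v[S.VISIT_DATE],
                    v[S.VISIT_DATE] + pd.Timedelta(days=horizon_days),
                    S.COMPLICATION_TYPES,
                )
            ) else -1
            hypo = int(
                cohort.has_event_between(
                    pid, v[S.VISIT_DATE], nxt[S.VISIT_DATE], ["hypoglycemia_admission"]
                )
            )
            r = reward(
                treatment_type,
                RewardInputs(
                    next_hba1c=nxt["hba1c"],
                    next_sbp=nxt["sbp"],
                    next_dbp=nxt["dbp"],
                    next_ldl=nxt["ldl_c"],
                    hypo_before_next=hypo,
                    is_final=int(is_final),
                    cx_sign=cx,
                ),
                coef,
            )
            states.append(scheme.encode(v, prev_rx))
            next_states.append(
                np.full(scheme.width, np.nan)
                if is_final
                else scheme.encode(nxt, rx_seq[i])
            )
            actions.append(a)
            rewards_.append(r)
            terminals.append(is_final)
            pids.append(pid)
            dates.append(v[S.VISIT_DATE])

    if not states:
        warnings.warn(f"no transitions built for {treatment_type}", stacklevel=2)
        d = scheme.width
        return TransitionSet(
            treatment_type,
            np.empty((0, d)), np.empty(0, int), np.empty(0), np.empty((0, d)),
            np.empty(0, bool), np.empty(0, object), np.empty(0, object),
        )
    if n_uninferable:
        warnings.warn(
            f"{n_uninferable} transitions dropped: uninferable actions", stacklevel=2
        )
    return TransitionSet(
        treatment_type,
        np.asarray(states, float),
        np.asarray(actions, int),
        np.asarray(rewards_, float),
        np.asarray(next_states, float),
        np.asarray(terminals, bool),
        np.asarray(pids, object),
        np.asarray(dates, object),
    )
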