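"""State featurization: encode a visit into the 49-dimensional state vector.

The state groups the categories the Q-network consumes: demographics,
medical-history flags, rule-derived disease-risk flags, previous drugs
(per-drug-class indicators of the prescriptions currently in use), and labs /
physical measurements.  Continuous variables are min-max scaled to [0, 1]
using percentile bounds fitted on training data and clipped; binary variables
are 0/1; ethnicity is one-hot with an explicit "Other" level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import schema as S
from .actions import (
    ANTIHYPERTENSIVE_CLASSES,
    INSULIN_CLASSES,
    LIPID_CLASSES,
    OAD_CLASSES,
    Prescription,
)

RISK_FLAGS = (
    "risk_egfr_lt60",
    "risk_egfr_lt45",
    "risk_egfr_lt30",
    "risk_macrovascular",
    "risk_microvascular",
    "risk_hba1c_above_target",
    "risk_hba1c_gt9",
    "risk_bp_above_target",
    "risk_ldl_above_target",
)

DRUG_FLAGS = (
    tuple(f"prev_{c}" for c in OAD_CLASSES + INSULIN_CLASSES)
    + tuple(f"prev_{c}" for c in ANTIHYPERTENSIVE_CLASSES)
    + tuple(f"prev_{c}" for c in LIPID_CLASSES)
)

STATE_WIDTH = 49

# percentile bounds for continuous scaling
LOWER_PCT, UPPER_PCT = 0.5, 99.5


class FeaturizationError(ValueError):
    pass


def _risk_flags(row) -> dict:
    return {
        "risk_egfr_lt60": row["egfr"] < 60,
        "risk_egfr_lt45": row["egfr"] < 45,
        "risk_egfr_lt30": row["egfr"] < 30,
        "risk_macrovascular": any(row[f] for f in S.MACROVASCULAR_FLAGS),
        "risk_microvascular": any(row[f] for f in S.MICROVASCULAR_FLAGS),
        "risk_hba1c_above_target": row["hba1c"] >= 7.0,
        "risk_hba1c_gt9": row["hba1c"] > 9.0,
        "risk_bp_above_target": row["sbp"] >= 140.0 or row["dbp"] >= 90.0,
        "risk_ldl_above_target": row["ldl_c"] >= 2.6,
    }


@dataclass
class FeatureScheme:
    """Ordered feature list with fitted normalization bounds.

    ``bounds`` maps each continuous field to a (lower, upper) pair used for
    min-max scaling; values outside the bounds are clipped.
    """

    bounds: dict[str, tuple[float, float]]

    feature_names: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.feature_names = (
            S.CONTINUOUS_FIELDS
            + S.BINARY_FIELDS
            + tuple(f"ethnicity_{lv}" for lv in S.ETHNICITY_LEVELS)
            + S.HISTORY_FLAGS
            + RISK_FLAGS
            + DRUG_FLAGS
        )
        if len(self.feature_names) != STATE_WIDTH:
            raise FeaturizationError(
                f"scheme width {len(self.feature_names)} != {STATE_WIDTH}"
            )
        for col, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise FeaturizationError(f"degenerate bounds for {col!r}: ({lo}, {hi})")

    @property
    def width(self) -> int:
        return len(self.feature_names)

    def encode(self, row, prev_rx: dict[str, Prescription | None]) -> np.ndarray:
        """Encode one (imputed) visit row plus the prescriptions in use."""
        out = np.empty(self.width)
        i = 0
        for col in S.CONTINUOUS_FIELDS:
            lo, hi = self.bounds[col]
            v = float(row[col])
            if not np.isfinite(v):
                raise FeaturizationError(f"missing value in field {col!r}")
            out[i] = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
            i += 1
        for col in S.BINARY_FIELDS:
            out[i] = 1.0 if row[col] else 0.0
            i += 1
        eth = row[S.ETHNICITY_FIELD]
        if eth not in S.ETHNICITY_LEVELS:
            eth = "Other"
        for lv in S.ETHNICITY_LEVELS:
            out[i] = 1.0 if eth == lv else 0.0
            i += 1
        for col in S.HISTORY_FLAGS:
            out[i] = 1.0 if row[col] else 0.0
            i += 1
        risks = _risk_flags(row)
        for name in RISK_FLAGS:
            out[i] = 1.0 if risks[name] else 0.0
            i += 1
        classes = set()
        for rx in prev_rx.values():
            if rx is not None:
                classes |= rx.classes()
        for name in DRUG_FLAGS:
            out[i] = 1.0 if name.removeprefix("prev_") in classes else 0.0
            i += 1
        return out

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "width": self.width,
            "features": list(self.feature_names),
            "bounds": {k: [float(a), float(b)] for k, (a, b) in self.bounds.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls({k: (v[0], v[1]) for k, v in doc["bounds"].items()})

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(",".join(self.feature_names).encode())
        for col in S.CONTINUOUS_FIELDS:
            h.update(np.asarray(self.bounds[col]).tobytes())
        return h.hexdigest()[:16]


def fit_scheme(cohort) -> FeatureScheme:
    """Fit normalization bounds on a (non-empty, imputed) training cohort."""
    visits = cohort.visits
    if visits.empty:
        raise FeaturizationError("cannot fit a feature scheme on an empty cohort")
    bounds = {}
    for col in S.CONTINUOUS_FIELDS:
        vals = visits[col].dropna().to_numpy(float)
        if vals.size == 0:
            raise FeaturizationError(f"field {col!r} has no observed values")
        lo, hi = np.percentile(vals, [LOWER_PCT, UPPER_PCT])
        if not hi > lo:
            raise FeaturizationError(f"constant continuous feature {col!r}")
        bounds[col] = (float(lo), float(hi))
    return FeatureScheme(bounds)
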