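import numpy as np
import pandas as pd
import pytest

from t2dreco.cohort import impute_missing
from t2dreco.featurize import fit_scheme
from t2dreco.simulate import SimulatorConfig, as_cohort, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated registry (raw tables)."""
    cfg = SimulatorConfig(n_patients=120, seed=7)
    visits, outcomes = simulate_cohort(cfg)
    return cfg, visits, outcomes


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    _, visits, outcomes = small_sim
    return impute_missing(as_cohort(visits, outcomes))


@pytest.fixture(scope="session")
def small_scheme(small_cohort):
    return fit_scheme(small_cohort)


def make_visit_frame(rows):
    """Helper: build a visit table from minimal dicts, filling defaults."""
    defaults = {
        "age": 60.0, "gender_female": 0, "ethnicity": "Chinese", "smoker": 0,
        "diabetes_duration": 8.0, "hba1c": 8.0, "sbp": 130.0, "dbp": 75.0,
        "ldl_c": 2.5, "tg": 1.5, "bmi": 26.0, "egfr": 85.0,
        "hx_hypertension": 0, "hx_hypercholesterolemia": 0,
        "hx_myocardial_infarction": 0, "hx_heart_failure": 0, "hx_stroke": 0,
        "hx_nephropathy": 0, "hx_other_microvascular": 0, "hx_hypoglycemia": 0,
        "rx_antiglycemic": "metformin||1000",
        "rx_antihypertensive": "", "rx_lipid_lowering": "",
    }
    out = []
    for row in rows:
        d = dict(defaults)
        d.update(row)
        out.append(d)
    df = pd.DataFrame(out)
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    return df


def empty_outcomes():
    return pd.DataFrame(columns=["patient_id", "event_type", "event_date"])
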