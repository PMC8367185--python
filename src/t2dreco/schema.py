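"""Registry table schema: column names shared across modules.

The visit table has one row per outpatient visit. Prescription cells hold
the serialized prescription issued at that visit (see
:func:`t2dreco.actions.prescription_to_str`); an empty cell is a recorded
prescription of no drugs, a missing cell means no prescription record.
"""

PATIENT_ID = "patient_id"
VISIT_DATE = "visit_date"

CONTINUOUS_FIELDS = (
    "age",
    "diabetes_duration",
    "hba1c",
    "sbp",
    "dbp",
    "ldl_c",
    "tg",
    "bmi",
    "egfr",
)

# labs / physical measurements eligible for carry-forward + median imputation
IMPUTABLE_FIELDS = ("hba1c", "sbp", "dbp", "ldl_c", "tg", "bmi", "egfr")

# fields that must be strictly positive when present
POSITIVE_FIELDS = ("hba1c", "sbp", "dbp", "ldl_c", "egfr", "bmi")

BINARY_FIELDS = ("gender_female", "smoker")

ETHNICITY_FIELD = "ethnicity"
ETHNICITY_LEVELS = ("Chinese", "Malay", "Indian", "Other")

HISTORY_FLAGS = (
    "hx_hypertension",
    "hx_hypercholesterolemia",
    "hx_myocardial_infarction",
    "hx_heart_failure",
    "hx_stroke",
    "hx_nephropathy",
    "hx_other_microvascular",
    "hx_hypoglycemia",
)

MACROVASCULAR_FLAGS = ("hx_myocardial_infarction", "hx_heart_failure", "hx_stroke")
MICROVASCULAR_FLAGS = ("hx_nephropathy", "hx_other_microvascular")

RX_COLUMNS = {
    "antiglycemic": "rx_antiglycemic",
    "antihypertensive": "rx_antihypertensive",
    "lipid_lowering": "rx_lipid_lowering",
}

VISIT_COLUMNS = (
    (PATIENT_ID, VISIT_DATE)
    + CONTINUOUS_FIELDS
    + BINARY_FIELDS
    + (ETHNICITY_FIELD,)
    + HISTORY_FLAGS
    + tuple(RX_COLUMNS.values())
)

EVENT_TYPES = (
    "hypoglycemia_admission",
    "myocardial_infarction",
    "heart_failure",
    "stroke",
    "nephropathy",
    "other_microvascular",
    "death",
)
COMPLICATION_TYPES = EVENT_TYPES[1:]  # complications + death

OUTCOME_COLUMNS = (PATIENT_ID, "event_type", "event_date")

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25
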