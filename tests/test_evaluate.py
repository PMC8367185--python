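"""Evaluation statistics: 2x2 comparisons, propensity weighting, weighted
logistic ORs, stratification, long-term curves and risk scores."""

import numpy as np
import pandas as pd
import pytest

from t2dreco.evaluate import (
    EvaluationError,
    HBA1C_BANDS,
    compare_counts,
    concordance_rate,
    longterm_curves,
    longterm_regression,
    medication_pattern_histogram,
    propensity_weights,
    risk_score_model,
    short_term_compare,
    standardized_mean_differences,
    stratified_analysis,
    weighted_logistic_or,
)
from t2dreco.simulate import planted_or_samples


class TestShortTermCompare:
    def test_published_scale_counts_reproduce_incidences(self):
        """A 2x2 with 48,263/78,670 vs 21,507/99,819 events gives incidences
        61.35% and 21.55% and a crude OR near 5.78 (direct cross-ratio)."""
        res = compare_counts(78_670, 48_263, 99_819, 21_507)
        assert res.incidence_exposed == pytest.approx(0.6135, abs=5e-5)
        assert res.incidence_unexposed == pytest.approx(0.2155, abs=5e-5)
        # independent oracle: the cross-product ratio
        or_oracle = (48_263 / (78_670 - 48_263)) / (21_507 / (99_819 - 21_507))
        assert res.odds_ratio == pytest.approx(or_oracle, rel=1e-12)
        assert res.odds_ratio == pytest.approx(5.78, abs=0.01)
        assert res.p_value < 1e-100

    def test_null_identity(self):
        res = compare_counts(500, 100, 500, 100)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_haldane_correction_on_zero_cell(self):
        res = compare_counts(10, 0, 10, 5)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"exposure": [1, 1], "outcome": [0, 1]})
        with pytest.raises(EvaluationError):
            short_term_compare(df)


class TestPropensityWeighting:
    def test_balanced_independent_exposure_gives_weight_two(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame({
            "x0": rng.normal(size=n),
            "exposure": rng.integers(0, 2, n),
            "outcome": rng.integers(0, 2, n),
        })
        w = propensity_weights(df, ["x0"])
        assert np.abs(w - 2.0).mean() < 0.2

    def test_weighting_balances_confounded_covariates(self):
        df = planted_or_samples(8000, true_or=1.0, seed=3, confounding=1.0)
        covs = ["x0", "x1", "x2", "x3"]
        before = standardized_mean_differences(df, covs)
        w = propensity_weights(df, covs)
        after = standardized_mean_differences(df, covs, w)
        assert before.max() > 0.3           # confounding present
        assert after.max() < 0.1            # removed by weighting

    def test_null_effect_recovered_under_confounding(self):
        """With a planted null effect the naive OR is biased away from 1 but
        the IPW-adjusted CI covers 1."""
        df = planted_or_samples(20_000, true_or=1.0, seed=5, confounding=1.2)
        covs = ["x0", "x1", "x2", "x3"]
        naive = short_term_compare(df)
        w = propensity_weights(df, covs)
        adj = weighted_logistic_or(df, w, covs)
        assert naive.odds_ratio > 1.6
        assert adj.ci_low <= 1.0 <= adj.ci_high


class TestWeightedLogistic:
    def test_unit_weights_match_unweighted_logistic(self):
        df = planted_or_samples(3000, true_or=1.5, seed=7)
        a = weighted_logistic_or(df, np.ones(len(df)), ["x0", "x1"])
        import statsmodels.api as sm

        X = sm.add_constant(df[["exposure", "x0", "x1"]].astype(float))
        ref = sm.GLM(df["outcome"], X, family=sm.families.Binomial()).fit()
        assert a.coefficient == pytest.approx(float(ref.params["exposure"]), abs=1e-6)

    def test_or_is_exp_of_coefficient(self):
        df = planted_or_samples(3000, true_or=1.5, seed=8)
        a = weighted_logistic_or(df, np.ones(len(df)), [])
        assert a.odds_ratio == pytest.approx(np.exp(a.coefficient))
        assert a.ci_low <= a.odds_ratio <= a.ci_high

    def test_nonpositive_weights_rejected(self):
        df = planted_or_samples(100, true_or=1.5, seed=9)
        with pytest.raises(EvaluationError):
            weighted_logistic_or(df, np.zeros(len(df)), [])


class TestStratification:
    def _df(self):
        rng = np.random.default_rng(1)
        n = 3000
        hba1c = rng.uniform(5.5, 11.5, n)
        return pd.DataFrame({
            "hba1c": hba1c,
            "x0": rng.normal(size=n),
            "exposure": rng.integers(0, 2, n),
            "outcome": rng.integers(0, 2, n),
        })

    def test_band_boundaries(self):
        bands = HBA1C_BANDS
        def band_of(h):
            return next(name for lo, hi, name in bands if lo <= h < hi)
        assert band_of(6.9) == "low"
        assert band_of(7.0) == "medium"
        assert band_of(8.99) == "medium"
        assert band_of(9.0) == "high"

    def test_three_bands_three_results(self):
        out = stratified_analysis(self._df(), ["x0"])
        assert set(out) == {"low", "medium", "high"}
        assert all(v is not None for v in out.values())

    def test_empty_stratum_reported_absent(self):
        df = self._df()
        df = df[df["hba1c"] >= 7.0]
        out = stratified_analysis(df, ["x0"])
        assert out["low"] is None


class TestConcordanceRate:
    def test_exact_ratios(self):
        assert concordance_rate([1, 1, 1, 0, 0]) == pytest.approx(0.6)
        assert concordance_rate([True] * 4) == 1.0
        assert concordance_rate([False] * 3) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            concordance_rate([])


class TestLongtermCurves:
    def test_closed_form_slope(self):
        """Three bin points (0.1,0.5),(0.5,0.3),(0.9,0.1) fit slope -0.5."""
        rates = np.repeat([0.1, 0.5, 0.9], 200)
        outcomes = np.concatenate([
            np.r_[np.ones(100), np.zeros(100)],   # 0.5
            np.r_[np.ones(60), np.zeros(140)],    # 0.3
            np.r_[np.ones(20), np.zeros(180)],    # 0.1
        ])
        fit = longterm_curves(rates, outcomes, bin_width=0.2)
        assert fit.slope == pytest.approx(-0.5, abs=1e-9)

    def test_constant_occurrence_zero_slope(self):
        rates = np.tile([0.1, 0.3, 0.5, 0.7, 0.9], 50)
        outcomes = np.tile([1, 0], 125)[:250]
        fit = longterm_curves(rates, np.random.default_rng(0).permutation(outcomes))
        # occurrence equal in expectation; slope near zero by construction
        rates2 = np.repeat([0.1, 0.5, 0.9], 100)
        outcomes2 = np.tile([1, 0], 150)
        fit2 = longterm_curves(rates2, outcomes2)
        assert fit2.slope == pytest.approx(0.0, abs=1e-9)

    def test_bin_counts_partition_patients(self):
        rng = np.random.default_rng(2)
        rates = rng.random(500)
        fit = longterm_curves(rates, rng.integers(0, 2, 500))
        assert fit.counts.sum() == 500

    def test_single_bin_slope_undefined(self):
        with pytest.raises(EvaluationError):
            longterm_curves([0.15] * 10, [0, 1] * 5)


class TestLongtermRegression:
    @staticmethod
    def _planted(n=5000, protective=True, seed=0):
        rng = np.random.default_rng(seed)
        rates = {f"rate_{t}": rng.random(n)
                 for t in ("antiglycemic", "antihypertensive", "lipid_lowering")}
        risk = rng.random(n)
        lin = -1.0 + 2.0 * risk
        if protective:
            lin = lin - 1.2 * (rates["rate_antiglycemic"]
                               + rates["rate_antihypertensive"]
                               + rates["rate_lipid_lowering"])
        y = rng.random(n) < 1 / (1 + np.exp(-lin))
        return pd.DataFrame({**rates, "risk_score": risk, "outcome": y.astype(int)})

    def test_planted_protective_signs(self):
        res = longterm_regression(self._planted(protective=True))
        rate_terms = [t for t in res.index if t.startswith("rate_")]
        assert (res.loc[rate_terms, "coefficient"] < 0).all()
        assert res.loc["risk_score", "coefficient"] > 0
        assert (res.loc[rate_terms, "p_value"] < 0.01).all()

    def test_null_rates_near_zero(self):
        res = longterm_regression(self._planted(protective=False, seed=1))
        rate_terms = [t for t in res.index if t.startswith("rate_")]
        z = res.loc[rate_terms, "coefficient"] / res.loc[rate_terms, "std_error"]
        assert (z.abs() < 3).all()

    def test_patient_missing_a_rate_excluded(self):
        df = self._planted(n=200)
        df.loc[0, "rate_lipid_lowering"] = np.nan
        res_n = longterm_regression(df)
        assert res_n is not None  # row silently excluded
        df2 = df.dropna()
        pd.testing.assert_frame_equal(longterm_regression(df2), res_n)


class TestRiskScore:
    @staticmethod
    def _features(n, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        return rng, X

    def test_known_signal_discriminates(self):
        rng, X = self._features(5000)
        lin = 1.5 * X["a"] - 1.0 * X["b"]
        y = (rng.random(5000) < 1 / (1 + np.exp(-lin))).astype(int)
        from sklearn.metrics import roc_auc_score

        scores = risk_score_model(X, y, seed=0)
        assert roc_auc_score(y, scores) > 0.7
        assert np.all((scores >= 0) & (scores <= 1))

    def test_null_signal_auc_half(self):
        rng, X = self._features(5000, seed=1)
        y = rng.integers(0, 2, 5000)
        from sklearn.metrics import roc_auc_score

        scores = risk_score_model(X, y, seed=0)
        assert abs(roc_auc_score(y, scores) - 0.5) < 0.05

    def test_degenerate_outcome_rejected(self):
        _, X = self._features(100)
        with pytest.raises(EvaluationError):
            risk_score_model(X, np.zeros(100, int))

    def test_logistic_fallback(self):
        rng, X = self._features(800, seed=2)
        y = (rng.random(800) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        scores = risk_score_model(X, y, method="logistic", seed=0)
        assert np.all((scores >= 0) & (scores <= 1))


class TestMedicationPattern:
    def _visits(self, rows):
        df = pd.DataFrame(rows)
        df["hba1c"] = df["hba1c"].astype(float)
        return df

    def test_intensity_coding_cells(self):
        rows = [
            {"hba1c": 6.5, "rx_antiglycemic": "metformin||1000;sulfonylurea||40;basal_insulin||20"},
            {"hba1c": 6.5, "rx_antiglycemic": ""},
            {"hba1c": 8.0, "rx_antiglycemic": "premixed_insulin||30"},
            {"hba1c": 9.5, "rx_antiglycemic": "basal_insulin||20;prandial_insulin||12"},
        ]
        hist = medication_pattern_histogram(self._visits(rows))
        cells = {(r.band, r.n_oads, r.insulin_intensity): r.count
                 for r in hist.itertuples()}
        assert cells[("low", 2, 1)] == 1    # 2 OADs + basal -> (2, 1)
        assert cells[("low", 0, 0)] == 1    # no drugs -> (0, 0)
        assert cells[("medium", 0, 2)] == 1  # premix alone -> (0, 2)
        assert cells[("high", 0, 2)] == 1   # basal+prandial -> (0, 2)

    def test_missing_rx_record_skipped(self):
        rows = [{"hba1c": 6.5, "rx_antiglycemic": np.nan}]
        hist = medication_pattern_histogram(self._visits(rows))
        assert hist.empty


class TestBuildOutcomeCohort:
    @staticmethod
    def _cohort_and_recs(top_action=0):
        import pandas as pd
        from t2dreco.cohort import Cohort, impute_missing
        from t2dreco.evaluate import build_outcome_cohort  # noqa: F401
        from t2dreco.recommend import Recommendation
        from conftest import empty_outcomes, make_visit_frame

        rows = [
            {"patient_id": "A", "visit_date": "2015-01-01", "hba1c": 8.0},
            {"patient_id": "A", "visit_date": "2015-05-01", "hba1c": 6.5},
            {"patient_id": "A", "visit_date": "2015-09-01", "hba1c": 7.5},
            # B's second visit is only 1 month later: no qualifying follow-up
            {"patient_id": "B", "visit_date": "2015-01-01", "hba1c": 9.0},
            {"patient_id": "B", "visit_date": "2015-02-01", "hba1c": 8.5},
        ]
        cohort = impute_missing(Cohort(make_visit_frame(rows), empty_outcomes()))
        recs = {}
        for pid in cohort.patients():
            for _, row in cohort.visits_of(pid).iterrows():
                recs[(pid, row["visit_date"])] = Recommendation(
                    pid, row["visit_date"], "antiglycemic",
                    ((top_action, 1.0, True),), 1,
                )
        return cohort, recs

    def test_imputed_followup_lab_excluded(self):
        """A visit whose follow-up HbA1c had to be imputed carries no
        short-term outcome information and is dropped."""
        import numpy as np
        from t2dreco.cohort import Cohort, impute_missing
        from t2dreco.evaluate import SHORT_TERM_SPECS, build_outcome_cohort
        from t2dreco.recommend import Recommendation
        from conftest import empty_outcomes, make_visit_frame

        rows = [
            {"patient_id": "A", "visit_date": "2015-01-01", "hba1c": 8.0},
            {"patient_id": "A", "visit_date": "2015-05-01", "hba1c": 6.5},
            {"patient_id": "A", "visit_date": "2015-09-01", "hba1c": np.nan},
            {"patient_id": "B", "visit_date": "2015-01-01", "hba1c": 9.0},
            {"patient_id": "B", "visit_date": "2015-05-01", "hba1c": 8.0},
        ]
        cohort = impute_missing(Cohort(make_visit_frame(rows), empty_outcomes()))
        # A's first action (start metformin = 5) is recommended; B's is not
        tops = {"A": 5, "B": 7}
        recs = {}
        for pid, top in tops.items():
            for _, row in cohort.visits_of(pid).iterrows():
                recs[(pid, row["visit_date"])] = Recommendation(
                    pid, row["visit_date"], "antiglycemic", ((top, 1.0, True),), 1,
                )
        df = build_outcome_cohort(cohort, recs, SHORT_TERM_SPECS["hba1c_control"])
        # A's May->Sep pair is dropped (outcome lab imputed); Jan pairs stay
        assert len(df) == 2
        a = df[df["patient_id"] == "A"].iloc[0]
        b = df[df["patient_id"] == "B"].iloc[0]
        assert a["exposure"] == 1 and a["outcome"] == 1   # 6.5 < 7
        assert b["exposure"] == 0 and b["outcome"] == 0   # 8.0 >= 7

    def test_partition_and_followup_window(self):
        import numpy as np
        from t2dreco.evaluate import SHORT_TERM_SPECS, build_outcome_cohort

        cohort, recs = self._cohort_and_recs(top_action=0)
        # make A's first visit nonconcordant (recommend an addition instead)
        from t2dreco.recommend import Recommendation
        import pandas as pd

        key = ("A", pd.Timestamp("2015-01-01"))
        recs[key] = Recommendation("A", key[1], "antiglycemic",
                                   ((7, 1.0, True),), 1)
        spec = SHORT_TERM_SPECS["hba1c_control"]
        df = build_outcome_cohort(cohort, recs, spec)
        # A contributes two qualifying visits (Jan->May, May->Sep); B none
        assert len(df) == 2
        assert set(df["patient_id"]) == {"A"}
        jan = df.iloc[0]
        assert jan["exposure"] == 0          # recommended 7, physician did 0
        assert jan["outcome"] == 1           # next HbA1c 6.5 < 7
        may = df.iloc[1]
        assert may["exposure"] == 1 and may["outcome"] == 0
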