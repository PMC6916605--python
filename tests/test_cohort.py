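"""Eligibility cascade, index dates, grade bands and baseline covariates."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duotherapy.cohort import (apply_eligibility, bp_grade,
                               extract_baseline_covariates, find_index_dates)
from duotherapy.config import EligibilityConfig

from conftest import make_bp, make_events, make_patients, make_prescriptions

IDX = 2500  # a day well inside the 2006-2014 window


def candidates_of(rows, config):
    return find_index_dates(make_prescriptions(rows), config)


class TestFindIndexDates:
    def test_single_record_is_simplest_initiation(self, eligibility_config):
        cand = candidates_of([(1, "ACEi", IDX, 28)], eligibility_config)
        assert len(cand) == 1
        row = cand.iloc[0]
        assert row["index_date"] == IDX
        assert row["initial_classes"] == ("ACEi",)
        assert row["group"] == "monotherapy"
        assert bool(row["washout_ok"])

    def test_same_day_pair_is_two_drug_regimen(self, eligibility_config):
        cand = candidates_of([(1, "ACEi", IDX, 28), (1, "CCB", IDX, 28)],
                             eligibility_config)
        row = cand.iloc[0]
        assert row["initial_classes"] == ("ACEi", "CCB")
        assert row["group"] == "two_drug"

    def test_washout_measured_from_prior_supply_end(self):
        # pre-window TZD supply ends at day IDX-100: gap 100 < 183 -> not
        # a new user at the first in-window prescription
        config = EligibilityConfig(study_start=IDX - 50, study_end=IDX + 500)
        cand = candidates_of([(1, "TZD", IDX - 128, 28), (1, "BB", IDX, 28)],
                             config)
        assert cand.iloc[0]["index_date"] == IDX
        assert not bool(cand.iloc[0]["washout_ok"])

    def test_washout_boundary_gap_exactly_183_is_clean(self):
        config = EligibilityConfig(study_start=IDX - 50, study_end=IDX + 500)
        cand = candidates_of([(1, "TZD", IDX - 183 - 28, 28),
                              (1, "BB", IDX, 28)], config)
        assert bool(cand.iloc[0]["washout_ok"])
        cand = candidates_of([(1, "TZD", IDX - 182 - 28, 28),
                              (1, "BB", IDX, 28)], config)
        assert not bool(cand.iloc[0]["washout_ok"])

    def test_three_classes_flagged(self, eligibility_config):
        cand = candidates_of([(1, "ACEi", IDX, 28), (1, "CCB", IDX, 28),
                              (1, "TZD", IDX, 28)], eligibility_config)
        assert bool(cand.iloc[0]["too_many_classes"])

    def test_out_of_window_prescriptions_yield_no_candidate(
            self, eligibility_config):
        cand = candidates_of([(1, "ACEi", 100, 28)], eligibility_config)
        assert cand.empty

    def test_duplicates_deduplicated(self, eligibility_config):
        cand = candidates_of([(1, "ACEi", IDX, 28), (1, "ACEi", IDX, 28)],
                             eligibility_config)
        assert len(cand) == 1
        assert cand.iloc[0]["initial_classes"] == ("ACEi",)


def _eligible_streams(pid=1, idx=IDX, sbp=150, dbp=85,
                      extra_events=(), extra_bp=()):
    """A minimal fully-eligible patient plus optional extra records."""
    patients = make_patients([(pid, idx - 1000, idx + 800)])
    bp = make_bp([(pid, idx - 30, sbp, dbp), (pid, idx - 200, 162, 96),
                  *extra_bp])
    events = make_events([(pid, idx - 400, "hypertension_dx"), *extra_events])
    return {"patients": patients, "bp": bp, "events": events,
            "prescriptions": make_prescriptions([(pid, "ACEi", idx, 28)])}


def run_cascade(streams, config):
    cand = find_index_dates(streams["prescriptions"], config)
    return apply_eligibility(cand, streams, config)


class TestApplyEligibility:
    def test_fully_eligible_patient_passes(self, eligibility_config):
        cohort, attrition = run_cascade(_eligible_streams(), eligibility_config)
        assert len(cohort) == 1
        assert cohort.iloc[0]["baseline_sbp"] == 150
        assert cohort.iloc[0]["hypertension_grade"] == 1

    @pytest.mark.parametrize("sbp, dbp, grade", [
        (150, 85, 1),    # SBP band 1, DBP band 0
        (150, 92, 1),
        (165, 85, 2),
        (150, 102, 2),   # DBP band dominates
        (185, 85, 3),
        (150, 112, 3),
    ])
    def test_grade_assignment(self, sbp, dbp, grade, eligibility_config):
        cohort, _ = run_cascade(_eligible_streams(sbp=sbp, dbp=dbp),
                                eligibility_config)
        assert cohort.iloc[0]["hypertension_grade"] == grade

    def test_recent_mi_excludes_old_mi_retained(self, eligibility_config):
        recent, _ = run_cascade(_eligible_streams(
            extra_events=[(1, IDX - 200, "myocardial_infarction", "hospital")]),
            eligibility_config)
        assert recent.empty
        old, _ = run_cascade(_eligible_streams(
            extra_events=[(1, IDX - 400, "myocardial_infarction", "hospital")]),
            eligibility_config)
        assert len(old) == 1

    def test_heart_failure_any_time_excludes(self, eligibility_config):
        cohort, _ = run_cascade(_eligible_streams(
            extra_events=[(1, IDX - 900, "heart_failure", "hospital")]),
            eligibility_config)
        assert cohort.empty

    def test_no_recent_bp_measure_excludes(self, eligibility_config):
        streams = _eligible_streams()
        streams["bp"] = make_bp([(1, IDX - 150, 162, 96),
                                 (1, IDX - 200, 158, 94)])
        cohort, attrition = run_cascade(streams, eligibility_config)
        assert cohort.empty
        row = attrition.set_index("criterion").loc[
            "elevated BP within short lookback"]
        assert row["n_excluded"] == 1

    def test_evidence_from_repeated_elevated_without_diagnosis(
            self, eligibility_config):
        streams = _eligible_streams()
        streams["events"] = make_events([])  # no diagnosis code
        cohort, _ = run_cascade(streams, eligibility_config)
        assert len(cohort) == 1  # two elevated readings within the year
        streams["bp"] = make_bp([(1, IDX - 30, 150, 85)])  # only one reading
        cohort, _ = run_cascade(streams, eligibility_config)
        assert cohort.empty

    def test_short_history_excludes(self, eligibility_config):
        streams = _eligible_streams()
        streams["patients"] = make_patients([(1, IDX - 200, IDX + 800)])
        cohort, _ = run_cascade(streams, eligibility_config)
        assert cohort.empty

    def test_attrition_telescopes(self, eligibility_config):
        streams = _eligible_streams()
        _, attrition = run_cascade(streams, eligibility_config)
        n = attrition["n_before"].iloc[0]
        for _, row in attrition.iterrows():
            assert row["n_after"] == row["n_before"] - row["n_excluded"]
            assert row["n_before"] == n
            n = row["n_after"]

    def test_baseline_bp_always_elevated(self, eligibility_config):
        cohort, _ = run_cascade(_eligible_streams(), eligibility_config)
        elevated = (cohort["baseline_sbp"] >= 140) | (cohort["baseline_dbp"] >= 90)
        assert elevated.all()

    def test_wider_washout_shrinks_or_preserves_cohort(self):
        # patient A: clean; patient B: prior use 200 days before index
        rx = make_prescriptions([
            (1, "ACEi", IDX, 28), (2, "ACEi", IDX, 28),
            (2, "TZD", IDX - 228, 28)])
        streams = {
            "patients": make_patients([(1, IDX - 1000, IDX + 800),
                                       (2, IDX - 1000, IDX + 800)]),
            "bp": make_bp([(p, IDX - 30, 150, 95) for p in (1, 2)]
                          + [(p, IDX - 200, 162, 96) for p in (1, 2)]),
            "events": make_events([(p, IDX - 400, "hypertension_dx")
                                   for p in (1, 2)]),
            "prescriptions": rx}
        wide = EligibilityConfig(washout_days=365, study_start=IDX - 150,
                                 study_end=IDX + 100)
        narrow = EligibilityConfig(washout_days=183, study_start=IDX - 150,
                                   study_end=IDX + 100)
        c_wide, _ = run_cascade(streams, wide)
        c_narrow, _ = run_cascade(streams, narrow)
        assert set(c_wide["patient_id"]) <= set(c_narrow["patient_id"])
        assert set(c_narrow["patient_id"]) == {1, 2}
        assert set(c_wide["patient_id"]) == {1}


class TestGradeProperty:
    @settings(max_examples=200, derandomize=True)
    @given(st.integers(min_value=60, max_value=280),
           st.integers(min_value=30, max_value=180))
    def test_grade_is_max_of_band_grades(self, sbp, dbp):
        def band(x, lo, mid, hi):
            return 3 if x >= hi else 2 if x >= mid else 1 if x >= lo else 0

        expected = max(band(sbp, 140, 160, 180), band(dbp, 90, 100, 110))
        assert bp_grade(sbp, dbp) == expected


class TestBaselineCovariates:
    def test_no_prior_use_gives_zero_indicators(self, eligibility_config):
        streams = _eligible_streams()
        cohort, _ = run_cascade(streams, eligibility_config)
        cov = extract_baseline_covariates(cohort, streams, eligibility_config)
        row = cov.iloc[0]
        assert row["prior_antihtn"] == 0
        assert row["prior_antihtn_n_classes"] == 0
        assert row["prior_antihtn_months_since"] == 0

    def test_months_since_last_prewashout_prescription(self, eligibility_config):
        streams = _eligible_streams()
        # last supply ends 18 months (548 days) before the index
        streams["prescriptions"] = pd.concat([
            streams["prescriptions"],
            make_prescriptions([(1, "TZD", IDX - 548 - 28, 28),
                                (1, "BB", IDX - 600 - 28, 28)])],
            ignore_index=True)
        cohort, _ = run_cascade(streams, eligibility_config)
        cov = extract_baseline_covariates(cohort, streams, eligibility_config)
        row = cov.iloc[0]
        assert row["prior_antihtn"] == 1
        assert row["prior_antihtn_n_classes"] == 2
        assert row["prior_antihtn_months_since"] == pytest.approx(18.0, abs=0.1)

    def test_utilization_counts(self, eligibility_config):
        streams = _eligible_streams(extra_events=[
            (1, IDX - 50, "other_comorbidity", "primary_care"),
            (1, IDX - 90, "other_comorbidity", "hospital", None, 3)])
        cohort, _ = run_cascade(streams, eligibility_config)
        cov = extract_baseline_covariates(cohort, streams, eligibility_config)
        row = cov.iloc[0]
        # GP contacts: the 2 pre-index BP dates + 1 primary-care event
        assert row["gp_visits_1y"] == 3
        assert row["hosp_days_1y"] == 3

    def test_history_recency_strata(self, eligibility_config):
        streams = _eligible_streams(extra_events=[
            (1, IDX - 400, "diabetes"), (1, IDX - 100, "angina_ihd")])
        cohort, _ = run_cascade(streams, eligibility_config)
        cov = extract_baseline_covariates(cohort, streams, eligibility_config)
        row = cov.iloc[0]
        assert (row["hist_diabetes_ever"], row["hist_diabetes_1y"]) == (1, 0)
        assert (row["hist_angina_ever"], row["hist_angina_1y"]) == (1, 1)
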