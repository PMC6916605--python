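"""Endpoint rules, incidence rates, Cox and Kaplan-Meier estimation."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from duotherapy.dates import DAYS_PER_YEAR
from duotherapy.survival import (derive_bp_control, derive_mace, fit_cox,
                                 incidence_rate, km_curve, _subgroup_filter)

from conftest import make_bp, make_events, make_patients


def _followup(pid=1, idx=0, end=365, reason="registration_end"):
    return pd.DataFrame({"patient_id": [pid], "followup_end": [end],
                         "censor_reason": [reason]})


def _cohort(pid=1, idx=0):
    return pd.DataFrame({"patient_id": [pid], "index_date": [idx]})


class TestDeriveBPControl:
    def test_first_controlled_reading_is_the_event(self):
        bp = make_bp([(1, 30, 150, 92), (1, 90, 135, 85), (1, 120, 130, 80)])
        rec = derive_bp_control(_cohort(), bp, _followup())
        assert rec.iloc[0]["event"] == 1
        assert rec.iloc[0]["time"] == 90

    def test_conjunction_requires_both_thresholds(self):
        bp = make_bp([(1, 30, 138, 92)])  # DBP fails
        rec = derive_bp_control(_cohort(), bp, _followup())
        assert rec.iloc[0]["event"] == 0
        assert rec.iloc[0]["time"] == 365

    def test_no_post_index_reading_censors_at_followup_end(self):
        bp = make_bp([(1, -10, 130, 80)])  # controlled but pre-index
        rec = derive_bp_control(_cohort(), bp, _followup())
        assert rec.iloc[0]["event"] == 0
        assert rec.iloc[0]["censor_reason"] == "registration_end"

    def test_reading_after_followup_end_does_not_count(self):
        bp = make_bp([(1, 400, 130, 80)])
        rec = derive_bp_control(_cohort(), bp, _followup(end=365))
        assert rec.iloc[0]["event"] == 0


class TestDeriveMACE:
    def _run(self, events, death=None, death_cv=None, end=365):
        patients = make_patients([(1, -400, 800, death, death_cv)])
        return derive_mace(_cohort(), events, patients, _followup(end=end))

    def test_mi_without_death_is_nonfatal(self):
        ev = make_events([(1, 100, "myocardial_infarction", "hospital")])
        rec = self._run(ev)
        assert rec.iloc[0]["event"] == 1
        assert rec.iloc[0]["mace_subtype"] == "nonfatal_mi"
        assert rec.iloc[0]["time"] == 100

    def test_stroke_with_cv_death_within_30d_counts_at_death_date(self):
        ev = make_events([(1, 100, "stroke", "hospital")])
        rec = self._run(ev, death=120, death_cv=True)
        assert rec.iloc[0]["mace_subtype"] == "cv_death"
        assert rec.iloc[0]["time"] == 120

    def test_death_past_30d_window_keeps_event_nonfatal(self):
        ev = make_events([(1, 100, "myocardial_infarction", "hospital")])
        rec = self._run(ev, death=140, death_cv=False)
        assert rec.iloc[0]["mace_subtype"] == "nonfatal_mi"
        assert rec.iloc[0]["time"] == 100

    @pytest.mark.parametrize("death_day, subtype, time", [
        (129, "cv_death", 129),     # 29 days after the event: fatal
        (130, "cv_death", 130),     # exactly 30 days: still fatal
        (131, "nonfatal_mi", 100),  # 31 days: nonfatal at the event date
    ])
    def test_30_day_rule_boundaries(self, death_day, subtype, time):
        ev = make_events([(1, 100, "myocardial_infarction", "hospital")])
        rec = self._run(ev, death=death_day, death_cv=True)
        assert rec.iloc[0]["mace_subtype"] == subtype
        assert rec.iloc[0]["time"] == time

    def test_fatal_event_with_noncv_death_is_no_mace(self):
        ev = make_events([(1, 100, "stroke", "hospital")])
        rec = self._run(ev, death=110, death_cv=False)
        assert rec.iloc[0]["event"] == 0

    def test_cv_death_without_preceding_event(self):
        rec = self._run(make_events([]), death=200, death_cv=True)
        assert rec.iloc[0]["mace_subtype"] == "cv_death"
        assert rec.iloc[0]["time"] == 200

    def test_composite_takes_earliest_qualifying_event(self):
        ev = make_events([(1, 150, "stroke", "hospital"),
                          (1, 80, "myocardial_infarction", "hospital")])
        rec = self._run(ev)
        assert rec.iloc[0]["mace_subtype"] == "nonfatal_mi"
        assert rec.iloc[0]["time"] == 80


def _records(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestIncidenceRate:
    def test_zero_events_zero_rate_zero_lower_bound(self):
        est = incidence_rate(_records([100.0, 200.0], [0, 0]),
                             "patient_years", 1000.0)
        assert est.rate == 0.0
        assert est.ci_lower == 0.0
        assert est.ci_upper > 0

    def test_exact_poisson_interval_matches_chi_square_closed_form(self):
        # counts {0, 1, 35} against the Gamma/chi-square closed form
        pt = DAYS_PER_YEAR  # one patient-year in days
        cases = {0: (0.0, 3.6889), 1: (0.0253, 5.5716),
                 35: (24.3788, 48.6765)}
        for k, (lo, hi) in cases.items():
            df = _records([pt], [0]) if k == 0 else _records(
                [pt / k] * k, [1] * k)
            est = incidence_rate(df, "patient_years", 1.0)
            assert est.ci_lower == pytest.approx(lo, abs=2e-4)
            assert est.ci_upper == pytest.approx(hi, abs=2e-4)

    def test_table_style_rate_35_events_2809_patient_years(self):
        times = np.full(2809, DAYS_PER_YEAR)
        events = np.r_[np.ones(35), np.zeros(2809 - 35)]
        est = incidence_rate(_records(times, events), "patient_years", 1000.0)
        assert est.rate == pytest.approx(12.46, abs=0.005)
        assert est.ci_lower == pytest.approx(8.679, abs=0.005)
        assert est.ci_upper == pytest.approx(17.329, abs=0.005)

    def test_doubling_person_time_halves_rate(self):
        a = incidence_rate(_records([100.0] * 10, [1] * 10),
                           "patient_months", 100.0)
        b = incidence_rate(_records([200.0] * 10, [1] * 10),
                           "patient_months", 100.0)
        assert b.rate == pytest.approx(a.rate / 2)

    def test_zero_person_time_raises(self):
        with pytest.raises(ValueError):
            incidence_rate(_records([], []), "patient_months")

    def test_normal_approximation_above_cutoff(self):
        df = _records([1.0] * 200, [1] * 200)
        est = incidence_rate(df, "patient_days", 1.0, method="auto",
                             normal_cutoff=100)
        assert est.method == "normal"
        assert est.ci_lower == pytest.approx(1 - 1.96 / np.sqrt(200), rel=1e-6)


def _cox_df(times, events, treated, sets=None):
    df = pd.DataFrame({"time": times, "event": events, "treated": treated})
    df["set_id"] = sets if sets is not None else np.arange(len(df))
    df["patient_id"] = np.arange(len(df))
    return df


class TestFitCox:
    def test_identical_hazards_give_null_hr(self, rng):
        n = 3000
        t = rng.exponential(100, n)
        treated = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        est = fit_cox(_cox_df(t, np.ones(n, int), treated))
        assert est.hr == pytest.approx(1.0, abs=0.15)
        assert est.ci_lower < est.hr < est.ci_upper  # CI brackets the HR

    def test_no_events_in_one_arm_flagged_nonestimable(self):
        est = fit_cox(_cox_df([10, 20, 30, 40], [0, 0, 1, 1],
                              [1, 1, 0, 0]))
        assert not est.estimable

    def test_hand_solved_partial_likelihood_no_ties(self):
        # 6 subjects, event times all distinct; the no-ties Cox partial-
        # likelihood score is solved independently with a root finder and
        # must equal the fitted coefficient.
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        z = np.array([1, 0, 1, 0, 1, 0])

        def score(beta):
            s = 0.0
            for i in range(6):
                if events[i] == 0:
                    continue
                risk = times >= times[i]
                w = np.exp(beta * z[risk])
                s += z[i] - (w * z[risk]).sum() / w.sum()
            return s

        beta_hand = brentq(score, -5, 5)
        est = fit_cox(_cox_df(times, events, z), cluster_col=None)
        assert est.log_hr == pytest.approx(beta_hand, abs=1e-5)

    def test_time_varying_split_conserves_person_time(self):
        from duotherapy.survival import _tv_split

        df = _cox_df([100.0, 200.0, 50.0], [1, 0, 1], [1, 0, 1])
        ctrl = pd.Series({0: 40.0, 2: 80.0})  # patient 2's is past the end
        out = _tv_split(df, ctrl)
        tot = (out["time"] - out["entry"]).groupby(out["patient_id"]).sum()
        assert tot.to_dict() == {0: 100.0, 1: 200.0, 2: 50.0}
        split_rows = out[out["patient_id"] == 0].sort_values("entry")
        assert list(split_rows["bp_controlled"]) == [0, 1]
        assert list(split_rows["event"]) == [0, 1]

    def test_double_adjustment_covariate_enters_model(self, rng):
        n = 600
        x = rng.normal(size=n)
        treated = (rng.random(n) < 0.5).astype(int)
        t = rng.exponential(100 * np.exp(-0.5 * x))
        df = _cox_df(t, np.ones(n, int), treated)
        df["x"] = x
        est = fit_cox(df, adjust_covariates=["x"])
        assert est.adjusted == ("x",)
        assert est.estimable


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        rec = _cox_df([1.0, 2.0, 3.0], [1, 1, 1], [0, 0, 0])
        km = km_curve(rec, group_col="treated")
        surv = km.set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        rec = _cox_df([5.0, 6.0, 7.0], [0, 0, 0], [0, 0, 0])
        km = km_curve(rec, group_col="treated")
        assert (km["survival"] == 1.0).all()

    def test_mixed_fixture_matches_hand_product_limit(self):
        # events at 1, 3, 4, 6; censored at 2 and 5
        rec = _cox_df([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1], [0] * 6)
        km = km_curve(rec, group_col="treated").set_index("time")
        s = km["survival"]
        assert s.loc[1] == pytest.approx(5 / 6)
        assert s.loc[3] == pytest.approx(5 / 6 * 3 / 4)
        assert s.loc[4] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert s.loc[6] == pytest.approx(0.0)


class TestSubgroupFilter:
    def _cohort(self):
        return pd.DataFrame({
            "patient_id": range(6),
            "hypertension_grade": [1, 2, 3, 1, 2, 3],
            "initial_classes": [("ACEi",), ("CCB",), ("ACEi", "CCB"),
                                ("BB",), ("ACEi", "TZD"), ("TZD",)],
        })

    def test_all_is_identity(self):
        c = self._cohort()
        assert _subgroup_filter(c, "all") is c

    def test_grade_subgroups_partition_cohort(self):
        c = self._cohort()
        g1 = _subgroup_filter(c, "grade1")
        g23 = _subgroup_filter(c, "grade23")
        assert len(g1) + len(g23) == len(c)
        assert set(g1["patient_id"]) | set(g23["patient_id"]) \
            == set(c["patient_id"])

    def test_acei_ccb_subgroup_regimens(self):
        got = _subgroup_filter(self._cohort(), "acei_ccb")
        assert set(got["initial_classes"]) == {("ACEi",), ("CCB",),
                                              ("ACEi", "CCB")}
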