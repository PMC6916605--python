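import numpy as np
import pandas as pd
import pytest

from duotherapy.config import EligibilityConfig, EpisodeConfig


def make_prescriptions(rows):
    """rows: (patient_id, drug_class, start_date, supply_days[, fdc_id])"""
    recs = []
    for r in rows:
        pid, cls, start, supply = r[:4]
        fdc = r[4] if len(r) > 4 else None
        recs.append((pid, cls, start, supply, fdc))
    return pd.DataFrame(recs, columns=["patient_id", "drug_class",
                                       "start_date", "supply_days",
                                       "fixed_dose_combination_id"])


def make_patients(rows):
    """rows: (patient_id, reg_start, reg_end[, death_date[, death_cv]])"""
    recs = []
    for r in rows:
        pid, rs, re = r[:3]
        death = r[3] if len(r) > 3 else None
        cv = r[4] if len(r) > 4 else None
        recs.append((pid, "F", 1950, rs, re, death, cv, 27.0, 0, 3, "white"))
    df = pd.DataFrame(recs, columns=[
        "patient_id", "sex", "birth_year", "registration_start",
        "registration_end", "death_date", "death_cause_cv", "bmi", "smoking",
        "deprivation_index", "ethnicity"])
    df["death_date"] = df["death_date"].astype("Int64")
    return df


def make_bp(rows):
    """rows: (patient_id, date, sbp, dbp)"""
    return pd.DataFrame(rows, columns=["patient_id", "date", "sbp", "dbp"])


def make_events(rows):
    """rows: (patient_id, date, category[, source[, detail[, duration]]])"""
    recs = []
    for r in rows:
        pid, date, cat = r[:3]
        source = r[3] if len(r) > 3 else "primary_care"
        detail = r[4] if len(r) > 4 else None
        dur = r[5] if len(r) > 5 else None
        recs.append((pid, date, cat, source, detail, dur))
    return pd.DataFrame(recs, columns=["patient_id", "date", "category",
                                       "source", "detail", "duration_days"])


def empty_streams():
    return {"patients": make_patients([]), "prescriptions": make_prescriptions([]),
            "bp": make_bp([]), "events": make_events([])}


@pytest.fixture
def episode_config():
    return EpisodeConfig()


@pytest.fixture
def eligibility_config():
    return EligibilityConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
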