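"""New-user cohort construction: eligibility cascade and baseline covariates.

The cascade identifies, per patient, the first in-window antihypertensive
prescription (the index date), verifies new-user status over a washout
window measured from the end of the last prior supply, requires
registration history, evidence of hypertension and a recent elevated BP
measurement (which defines baseline BP and grade), and applies the
cardiovascular exclusions. Exclusion counts are sequential (cascade
order), so the attrition report telescopes exactly.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import DRUG_CLASSES, EligibilityConfig
from .dates import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

__all__ = ["find_index_dates", "apply_eligibility",
           "extract_baseline_covariates", "build_cohort", "bp_grade"]

HISTORY_CATEGORIES = ("myocardial_infarction", "stroke", "TIA", "angina_ihd",
                      "atrial_fibrillation", "diabetes", "pad", "ckd")


def bp_grade(sbp, dbp):
    """Hypertension grade 0-3: the max of the SBP band and the DBP band.

    Grade 1: 140-159 / 90-99; grade 2: 160-179 / 100-109; grade 3:
    >=180 / >=110 mmHg. Grade 0 means not elevated.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    gs = np.select([sbp >= 180, sbp >= 160, sbp >= 140], [3, 2, 1], default=0)
    gd = np.select([dbp >= 110, dbp >= 100, dbp >= 90], [3, 2, 1], default=0)
    out = np.maximum(gs, gd)
    return out if out.ndim else int(out)


def find_index_dates(prescriptions: pd.DataFrame,
                     config: EligibilityConfig) -> pd.DataFrame:
    """Identify candidate initiations (one per patient).

    The candidate index date is the patient's earliest prescription of
    any study class inside the study window; the initial regimen is the
    set of classes started on that date. ``washout_ok`` is False when any
    prior supply interval ends less than ``washout_days`` before the
    index (new-user violation) and ``too_many_classes`` is True when 3+
    classes start on the index date. Exact duplicate records are dropped
    and logged.
    """
    rx = prescriptions[prescriptions["drug_class"].isin(DRUG_CLASSES)].copy()
    dup = rx.duplicated(subset=["patient_id", "drug_class", "start_date",
                                "supply_days"])
    if dup.any():
        logger.info("dropping %d duplicate prescription records", int(dup.sum()))
        rx = rx[~dup]
    rx = rx.sort_values(["patient_id", "start_date"], kind="mergesort")
    rx["supply_end"] = rx["start_date"] + rx["supply_days"]

    in_window = rx[(rx["start_date"] >= config.study_start)
                   & (rx["start_date"] <= config.study_end)]
    first = (in_window.groupby("patient_id", sort=True)["start_date"]
             .min().rename("index_date").reset_index())

    rx = rx.merge(first, on="patient_id", how="inner")
    on_index = rx[rx["start_date"] == rx["index_date"]]
    regimen = (on_index.groupby("patient_id")["drug_class"]
               .agg(lambda s: tuple(sorted(set(s)))).rename("initial_classes"))
    prior = rx[rx["start_date"] < rx["index_date"]]
    last_prior_end = (prior.groupby("patient_id")["supply_end"].max()
                      .rename("last_prior_supply_end"))

    cand = first.set_index("patient_id").join([regimen, last_prior_end])
    cand["n_classes"] = cand["initial_classes"].map(len)
    gap = cand["index_date"] - cand["last_prior_supply_end"]
    cand["washout_ok"] = cand["last_prior_supply_end"].isna() | (
        gap >= config.washout_days)
    cand["too_many_classes"] = cand["n_classes"] >= 3
    cand["group"] = np.where(cand["n_classes"] == 2, "two_drug", "monotherapy")
    return cand.reset_index()


def _events_by_patient(events, categories):
    mask = events["category"].isin(categories)
    return events.loc[mask, ["patient_id", "date", "category"]]


def apply_eligibility(candidates: pd.DataFrame, streams: dict,
                      config: EligibilityConfig):
    """Apply the eligibility cascade; return (cohort, attrition report).

    The cohort keeps one row per patient with the index date, initial
    regimen, group, baseline BP (the most recent elevated measurement in
    the short lookback, index day included) and hypertension grade. The
    attrition report lists, in cascade order, the criterion label and the
    telescoping counts.
    """
    patients = streams["patients"].set_index("patient_id")
    bp = streams["bp"]
    events = streams["events"]

    steps = []
    df = candidates.copy()

    def record(label, kept):
        n_before = len(df)
        n_after = int(kept.sum())
        steps.append((label, n_before, n_before - n_after, n_after))
        return df[kept]

    steps.append(("in-window initiations", len(df), 0, len(df)))

    df = record("new user (washout clean)", df["washout_ok"])
    df = record("1 or 2 classes at index", ~df["too_many_classes"])

    reg_start = patients["registration_start"].reindex(df["patient_id"]).to_numpy()
    df = record(
        "registration history >= minimum",
        pd.Series(df["index_date"].to_numpy() - reg_start
                  >= config.min_history_days, index=df.index))

    # Hypertension evidence: diagnosis code at/before index OR repeated
    # elevated measures on distinct dates within the long lookback.
    bp_m = bp.merge(df[["patient_id", "index_date"]], on="patient_id")
    elevated = bp_m[(bp_m["sbp"] >= 140) | (bp_m["dbp"] >= 90)]
    rep = elevated[(elevated["date"] <= elevated["index_date"])
                   & (elevated["date"] > elevated["index_date"]
                      - config.repeated_bp_lookback_days)]
    n_rep = rep.groupby("patient_id")["date"].nunique()
    dx = _events_by_patient(events, ["hypertension_dx"]).merge(
        df[["patient_id", "index_date"]], on="patient_id")
    has_dx = set(dx.loc[dx["date"] <= dx["index_date"], "patient_id"])
    ok_ht = df["patient_id"].isin(has_dx) | (
        df["patient_id"].map(n_rep).fillna(0) >= config.min_repeated_elevated)
    df = record("hypertension evidence", ok_ht)

    # Recent elevated measurement defines baseline BP and grade.
    recent = elevated[(elevated["date"] <= elevated["index_date"])
                      & (elevated["date"] >= elevated["index_date"]
                         - config.elevated_bp_lookback_days)]
    recent = recent.sort_values(["patient_id", "date"]).groupby("patient_id").last()
    df = record("elevated BP within short lookback",
                df["patient_id"].isin(recent.index))
    df = df.merge(recent[["sbp", "dbp"]], left_on="patient_id",
                  right_index=True).reset_index(drop=True)
    df = df.rename(columns={"sbp": "baseline_sbp", "dbp": "baseline_dbp"})

    # Exclusions.
    sec = _events_by_patient(events, ["secondary_hypertension", "heart_failure"])
    sec = sec.merge(df[["patient_id", "index_date"]], on="patient_id")
    excl_ever = set(sec.loc[sec["date"] <= sec["index_date"], "patient_id"])
    df = record("no secondary hypertension / heart failure",
                ~df["patient_id"].isin(excl_ever))

    recent_cats = ["myocardial_infarction", "stroke"]
    if config.tia_exclusion:
        recent_cats.append("TIA")
    cv = _events_by_patient(events, recent_cats).merge(
        df[["patient_id", "index_date"]], on="patient_id")
    excl_recent = set(cv.loc[
        (cv["date"] <= cv["index_date"])
        & (cv["date"] > cv["index_date"] - config.mi_stroke_exclusion_days),
        "patient_id"])
    df = record("no stroke/MI in exclusion window",
                ~df["patient_id"].isin(excl_recent))

    df["hypertension_grade"] = bp_grade(df["baseline_sbp"], df["baseline_dbp"])
    df = df.drop(columns=["washout_ok", "too_many_classes"]).reset_index(drop=True)
    attrition = pd.DataFrame(
        steps, columns=["criterion", "n_before", "n_excluded", "n_after"])
    return df, attrition


def extract_baseline_covariates(cohort: pd.DataFrame, streams: dict,
                                config: EligibilityConfig) -> pd.DataFrame:
    """Attach every baseline covariate family to the cohort table.

    Families: demographics/lifestyle (age at index, sex, BMI, smoking,
    deprivation, ethnicity with an explicit missing category); baseline
    BP and grade; months since first hypertension diagnosis; medical
    history indicators with recency strata (ever / within 1 year); prior
    antihypertensive use before the washout (any, months since last
    supply end, number of distinct classes); comedication indicators in
    the prior year; GP-contact and hospitalization-day counts in the
    prior year; and prior follow-up duration. Missing values carry an
    explicit missing category or indicator, never NaN.
    """
    out = cohort.copy()
    patients = streams["patients"].set_index("patient_id")
    events = streams["events"]
    bp = streams["bp"]
    rx = streams["prescriptions"]
    pid = out["patient_id"]
    idx = out.set_index("patient_id")["index_date"]

    p = patients.reindex(pid).reset_index(drop=True)
    out["male"] = (p["sex"].to_numpy() == "M").astype(int)
    out["age"] = (out["index_date"] / 365.25 + 2000
                  - p["birth_year"].to_numpy()).round(1)
    out["bmi"] = p["bmi"].to_numpy()
    out["smoking"] = p["smoking"].to_numpy()
    out["deprivation_index"] = p["deprivation_index"].to_numpy()
    eth = p["ethnicity"].fillna("missing").to_numpy()
    out["ethnicity"] = eth
    out["prior_followup_days"] = (out["index_date"].to_numpy()
                                  - p["registration_start"].to_numpy())

    ev = events.merge(out[["patient_id", "index_date"]], on="patient_id")
    ev = ev[ev["date"] <= ev["index_date"]]
    ev["days_before"] = ev["index_date"] - ev["date"]

    # Months since first hypertension diagnosis (0 + indicator if none).
    dx = ev[ev["category"] == "hypertension_dx"].groupby("patient_id")[
        "days_before"].max()
    out["has_ht_dx"] = pid.isin(dx.index).astype(int)
    out["ht_months"] = (pid.map(dx).fillna(0) / DAYS_PER_MONTH).round(1)

    for cat in HISTORY_CATEGORIES:
        sub = ev[ev["category"] == cat]
        ever = set(sub["patient_id"])
        recent = set(sub.loc[sub["days_before"] < 365, "patient_id"])
        key = {"myocardial_infarction": "mi", "angina_ihd": "angina",
               "atrial_fibrillation": "af", "TIA": "tia"}.get(cat, cat)
        out[f"hist_{key}_ever"] = pid.isin(ever).astype(int)
        out[f"hist_{key}_1y"] = pid.isin(recent).astype(int)

    for detail in ("lipid_lowering", "antiplatelet", "antidiabetic"):
        sub = ev[(ev["category"] == "comedication_class")
                 & (ev["detail"] == detail) & (ev["days_before"] < 365)]
        out[f"comed_{detail}"] = pid.isin(set(sub["patient_id"])).astype(int)

    # Prior antihypertensive use strictly before the washout window.
    rx = rx.copy()
    rx["supply_end"] = rx["start_date"] + rx["supply_days"]
    rxm = rx.merge(out[["patient_id", "index_date"]], on="patient_id")
    prior = rxm[rxm["supply_end"] <= rxm["index_date"] - config.washout_days]
    last_end = prior.groupby("patient_id")["supply_end"].max()
    n_cls = prior.groupby("patient_id")["drug_class"].nunique()
    out["prior_antihtn"] = pid.isin(last_end.index).astype(int)
    out["prior_antihtn_months_since"] = (
        (idx.reindex(pid).to_numpy() - pid.map(last_end).to_numpy())
        / DAYS_PER_MONTH)
    out["prior_antihtn_months_since"] = (
        out["prior_antihtn_months_since"].fillna(0).round(1))
    out["prior_antihtn_n_classes"] = pid.map(n_cls).fillna(0).astype(int)

    # Utilization in the prior year: distinct primary-care contact dates
    # (BP readings and primary-care events) and hospitalization days.
    bpm = bp.merge(out[["patient_id", "index_date"]], on="patient_id")
    bpm = bpm[(bpm["date"] < bpm["index_date"])
              & (bpm["date"] >= bpm["index_date"] - 365)]
    pc = ev[(ev["source"] == "primary_care") & (ev["days_before"] < 365)
            & (ev["days_before"] > 0)]
    contacts = pd.concat([bpm[["patient_id", "date"]],
                          pc[["patient_id", "date"]]])
    n_gp = contacts.groupby("patient_id")["date"].nunique()
    out["gp_visits_1y"] = pid.map(n_gp).fillna(0).astype(int)
    hosp = ev[(ev["source"] == "hospital") & (ev["days_before"] < 365)]
    hosp_days = hosp.groupby("patient_id")["duration_days"].apply(
        lambda s: s.fillna(1).sum())
    out["hosp_days_1y"] = pid.map(hosp_days).fillna(0).astype(int)
    return out


def build_cohort(streams: dict, config: EligibilityConfig):
    """Full cohort-builder stage: candidates → eligibility → covariates."""
    candidates = find_index_dates(streams["prescriptions"], config)
    cohort, attrition = apply_eligibility(candidates, streams, config)
    cohort = extract_baseline_covariates(cohort, streams, config)
    return cohort, attrition
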