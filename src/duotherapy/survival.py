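"""Endpoint derivation, incidence rates, matched Cox models and KM curves.

Endpoints
---------
*BP control*: first measurement strictly after the index date with
SBP < 140 **and** DBP < 90 mmHg inside follow-up.

*MACE*: composite of acute nonfatal MI, nonfatal stroke and
cardiovascular death. An MI or stroke is nonfatal iff no death is
recorded within 30 days (inclusive) after its date; a fatal MI/stroke
contributes as cardiovascular death at the death date when the cause is
cardiovascular, and as no MACE otherwise.

Estimation
----------
Incidence rates carry exact Poisson (chi-square) 95% intervals, with a
normal approximation available above a documented count cutoff. Hazard
ratios come from Cox proportional-hazards fits (Efron ties) with a
robust sandwich variance clustered on the matched-set identifier, with
optional double adjustment for residually imbalanced covariates and an
optional time-varying BP-control indicator (follow-up split at the
first control date, delayed-entry rows).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .dates import DAYS_PER_MONTH, DAYS_PER_YEAR

__all__ = ["derive_bp_control", "derive_mace", "incidence_rate",
           "IncidenceEstimate", "HazardEstimate", "fit_cox", "km_curve",
           "run_comparison"]

UNIT_DAYS = {"patient_days": 1.0, "patient_months": DAYS_PER_MONTH,
             "patient_years": DAYS_PER_YEAR}


def derive_bp_control(cohort: pd.DataFrame, bp: pd.DataFrame,
                      followup: pd.DataFrame) -> pd.DataFrame:
    """Time to first controlled measurement (SBP<140 and DBP<90).

    The event date must satisfy ``index < date <= followup_end``;
    otherwise the record is censored at the follow-up end with the
    follow-up's censoring reason.
    """
    base = cohort[["patient_id", "index_date"]].merge(
        followup[["patient_id", "followup_end", "censor_reason"]],
        on="patient_id")
    m = bp.merge(base, on="patient_id")
    ctrl = m[(m["sbp"] < 140) & (m["dbp"] < 90)
             & (m["date"] > m["index_date"]) & (m["date"] <= m["followup_end"])]
    first = ctrl.groupby("patient_id")["date"].min()
    out = base.copy()
    ev_date = out["patient_id"].map(first)
    out["event"] = ev_date.notna().astype(int)
    end = ev_date.fillna(out["followup_end"])
    out["time"] = (end - out["index_date"]).clip(lower=0.5)
    out.loc[out["event"] == 1, "censor_reason"] = ""
    out["endpoint"] = "bp_control"
    return out[["patient_id", "index_date", "time", "event", "censor_reason",
                "endpoint"]]


def derive_mace(cohort: pd.DataFrame, events: pd.DataFrame,
                patients: pd.DataFrame, followup: pd.DataFrame,
                fatal_window_days: int = 30) -> pd.DataFrame:
    """Time to first MACE with the 30-day fatal/nonfatal adjudication."""
    base = cohort[["patient_id", "index_date"]].merge(
        followup[["patient_id", "followup_end", "censor_reason"]],
        on="patient_id")
    p = patients.set_index("patient_id")
    death = p["death_date"].reindex(base["patient_id"]).to_numpy("float")
    death_cv = (p["death_cause_cv"].reindex(base["patient_id"])
                .map(lambda v: bool(v) if pd.notna(v) else False)
                .to_numpy(dtype=bool))
    base["death_date"] = death
    base["death_cv"] = death_cv

    cand = events[events["category"].isin(["myocardial_infarction", "stroke"])]
    cand = cand.merge(base, on="patient_id")
    cand = cand[(cand["date"] > cand["index_date"])
                & (cand["date"] <= cand["followup_end"])]
    fatal = cand["death_date"].notna() & (
        cand["death_date"] - cand["date"] <= fatal_window_days)

    pieces = []
    nonfatal = cand[~fatal].copy()
    nonfatal["mace_date"] = nonfatal["date"]
    nonfatal["mace_subtype"] = np.where(
        nonfatal["category"] == "myocardial_infarction",
        "nonfatal_mi", "nonfatal_stroke")
    pieces.append(nonfatal[["patient_id", "mace_date", "mace_subtype"]])

    # Fatal MI/stroke: counts as CV death at the death date when the cause
    # is cardiovascular and the death falls inside follow-up; otherwise no
    # MACE from this event.
    fatal_cv = cand[fatal & cand["death_cv"]
                    & (cand["death_date"] <= cand["followup_end"])].copy()
    fatal_cv["mace_date"] = fatal_cv["death_date"].astype(int)
    fatal_cv["mace_subtype"] = "cv_death"
    pieces.append(fatal_cv[["patient_id", "mace_date", "mace_subtype"]])

    cvd = base[base["death_cv"] & base["death_date"].notna()
               & (base["death_date"] > base["index_date"])
               & (base["death_date"] <= base["followup_end"])].copy()
    cvd["mace_date"] = cvd["death_date"].astype(int)
    cvd["mace_subtype"] = "cv_death"
    pieces.append(cvd[["patient_id", "mace_date", "mace_subtype"]])

    allc = pd.concat(pieces, ignore_index=True)
    first = (allc.sort_values(["patient_id", "mace_date"])
             .groupby("patient_id").first())

    out = base.copy()
    ev_date = out["patient_id"].map(first["mace_date"]).astype(float)
    out["event"] = ev_date.notna().astype(int)
    out["mace_subtype"] = out["patient_id"].map(first["mace_subtype"])
    end = ev_date.fillna(out["followup_end"])
    out["time"] = (end - out["index_date"]).clip(lower=0.5)
    out.loc[out["event"] == 1, "censor_reason"] = ""
    out["endpoint"] = "mace"
    return out[["patient_id", "index_date", "time", "event", "mace_subtype",
                "censor_reason", "endpoint"]]


@dataclass
class IncidenceEstimate:
    events: int
    person_time: float
    unit: str
    denominator: float
    rate: float
    ci_lower: float
    ci_upper: float
    method: str


def incidence_rate(records: pd.DataFrame, unit: str = "patient_months",
                   denominator: float = 100.0, method: str = "exact",
                   normal_cutoff: int = 100) -> IncidenceEstimate:
    """Incidence rate with a 95% CI per ``denominator`` units of person-time.

    ``method='exact'`` uses the chi-square form of the exact Poisson
    interval: lower = chi2(0.025, 2k)/2, upper = chi2(0.975, 2k+2)/2.
    With ``method='auto'`` the normal approximation k ± 1.96·sqrt(k) is
    used above ``normal_cutoff`` events.
    """
    pt_days = float(records["time"].sum())
    if pt_days <= 0:
        raise ValueError("zero person-time")
    k = int(records["event"].sum())
    pt = pt_days / UNIT_DAYS[unit]
    if method == "auto" and k > normal_cutoff:
        lo, hi = k - 1.96 * np.sqrt(k), k + 1.96 * np.sqrt(k)
        used = "normal"
    else:
        lo = stats.chi2.ppf(0.025, 2 * k) / 2.0 if k > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * (k + 1)) / 2.0
        used = "exact_poisson"
    scale = denominator / pt
    return IncidenceEstimate(events=k, person_time=pt, unit=unit,
                             denominator=denominator, rate=k * scale,
                             ci_lower=lo * scale, ci_upper=hi * scale,
                             method=used)


@dataclass
class HazardEstimate:
    endpoint: str
    comparison: str
    hr: float
    ci_lower: float
    ci_upper: float
    log_hr: float
    robust_se: float
    p_value: float
    n_events_treated: int
    n_events_control: int
    adjusted: tuple
    estimable: bool = True


def _tv_split(df: pd.DataFrame, control_times: pd.Series) -> pd.DataFrame:
    """Split follow-up at each patient's first BP-control date.

    Produces delayed-entry rows with a 0→1 ``bp_controlled`` indicator;
    total person-time per patient is conserved.
    """
    tc = df["patient_id"].map(control_times)
    split = tc.notna() & (tc < df["time"])
    a = df[~split].copy()
    a["entry"] = 0.0
    a["bp_controlled"] = 0
    pre = df[split].copy()
    pre["entry"] = 0.0
    pre["bp_controlled"] = 0
    pre["event"] = 0
    pre["time"] = tc[split]
    post = df[split].copy()
    post["entry"] = tc[split]
    post["bp_controlled"] = 1
    return pd.concat([a, pre, post], ignore_index=True)


def fit_cox(records: pd.DataFrame, treat_col: str = "treated",
            cluster_col: str | None = "set_id", adjust_covariates=(),
            time_varying_bp_control: bool = False,
            bp_control_times: pd.Series | None = None,
            endpoint: str = "", comparison: str = "two_drug vs monotherapy",
            ) -> HazardEstimate:
    """Matched Cox PH fit with robust variance clustered on the set id.

    ``records`` needs ``time``, ``event``, the treatment column and (for
    clustering) the matched-set column. ``adjust_covariates`` adds main
    effects (double adjustment). When ``time_varying_bp_control`` is on,
    ``bp_control_times`` (days since index, indexed by patient_id) splits
    each follow-up at the first control date.
    """
    df = records.copy()
    n_ev_t = int(df.loc[df[treat_col] == 1, "event"].sum())
    n_ev_c = int(df.loc[df[treat_col] == 0, "event"].sum())
    if n_ev_t == 0 or n_ev_c == 0:
        return HazardEstimate(endpoint, comparison, np.nan, np.nan, np.nan,
                              np.nan, np.nan, np.nan, n_ev_t, n_ev_c,
                              tuple(adjust_covariates), estimable=False)
    cols = ["time", "event", treat_col, *adjust_covariates]
    entry_col = None
    if time_varying_bp_control:
        if bp_control_times is None:
            raise ValueError("bp_control_times required for the time-varying fit")
        df = _tv_split(df, bp_control_times)
        cols.append("bp_controlled")
        entry_col = "entry"
        cols.append("entry")
    if cluster_col is not None:
        cols.append(cluster_col)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[[*dict.fromkeys(cols)]], duration_col="time",
                event_col="event", cluster_col=cluster_col,
                entry_col=entry_col, robust=cluster_col is not None)
    s = cph.summary.loc[treat_col]
    return HazardEstimate(
        endpoint=endpoint, comparison=comparison,
        hr=float(s["exp(coef)"]),
        ci_lower=float(s["exp(coef) lower 95%"]),
        ci_upper=float(s["exp(coef) upper 95%"]),
        log_hr=float(s["coef"]), robust_se=float(s["se(coef)"]),
        p_value=float(s["p"]), n_events_treated=n_ev_t,
        n_events_control=n_ev_c, adjusted=tuple(adjust_covariates))


def km_curve(records: pd.DataFrame, group_col: str = "treated") -> pd.DataFrame:
    """Product-limit estimate per arm with the risk-set table."""
    out = []
    for g, grp in records.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(g))
        tab = kmf.event_table.copy()
        tab["survival"] = kmf.survival_function_.iloc[:, 0].reindex(tab.index)
        tab = tab.reset_index().rename(columns={"event_at": "time"})
        tab[group_col] = g
        out.append(tab[[group_col, "time", "at_risk", "observed", "censored",
                        "survival"]])
    return pd.concat(out, ignore_index=True)


SUBGROUPS = ("all", "grade1", "grade23", "acei_ccb")


def _subgroup_filter(cohort: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    if subgroup == "all":
        return cohort
    if subgroup == "grade1":
        return cohort[cohort["hypertension_grade"] == 1]
    if subgroup == "grade23":
        return cohort[cohort["hypertension_grade"] >= 2]
    if subgroup == "acei_ccb":
        keep = cohort["initial_classes"].map(
            lambda c: tuple(sorted(c)) in (("ACEi",), ("CCB",), ("ACEi", "CCB")))
        return cohort[keep]
    raise ValueError(f"unknown subgroup {subgroup!r}")


def run_comparison(cohort: pd.DataFrame, streams: dict, exposure: dict,
                   covariates, match_spec, subgroup: str = "all",
                   balance_threshold: float = 0.1) -> dict:
    """Subgroup-specific PS, match, endpoints and estimates.

    Re-fits the propensity model inside the subgroup, re-matches,
    derives both endpoints on the subgroup's follow-up, and assembles a
    results bundle: incidence rates per arm (BP control per 100
    patient-months, MACE per 1000 patient-years), hazard ratios (MACE
    additionally with the time-varying BP-control covariate), balance
    table and KM step tables. Too-small subgroups report
    ``{"estimable": False}`` instead of raising.
    """
    from .matching import _design_matrix, balance_report, fit_propensity, \
        greedy_match, matched_long

    sub = _subgroup_filter(cohort, subgroup).copy()
    sub["treated"] = (sub["group"] == "two_drug").astype(int)
    if sub["treated"].nunique() < 2 or sub["treated"].sum() < 5:
        return {"subgroup": subgroup, "estimable": False,
                "n": len(sub), "reason": "subgroup too small to match"}
    fit = fit_propensity(sub, covariates)
    matches = greedy_match(fit, match_spec)
    if matches.empty:
        return {"subgroup": subgroup, "estimable": False,
                "n": len(sub), "reason": "no matches within caliper"}
    long = matched_long(matches)
    matched = sub.merge(long, on="patient_id")

    rep = balance_report(sub, matched, covariates, ratio=match_spec.ratio,
                         threshold=balance_threshold)
    # Residually imbalanced covariates enter the Cox model as main effects;
    # categorical levels enter through their expanded indicator columns.
    X = _design_matrix(matched, covariates)
    adjust = [c for c in rep.loc[rep["exceeds_threshold"], "covariate"]
              if c in X.columns]
    matched = pd.concat(
        [matched, X[[c for c in adjust if c not in matched.columns]]], axis=1)

    followup = exposure["followup"]
    bp_rec = derive_bp_control(matched, streams["bp"], followup)
    mace_rec = derive_mace(matched, streams["events"], streams["patients"],
                           followup)
    keep = matched[["patient_id", "set_id", "treated", *adjust]]
    bp_rec = bp_rec.merge(keep, on="patient_id")
    mace_rec = mace_rec.merge(keep, on="patient_id")

    results = {"subgroup": subgroup, "estimable": True,
               "n_treated": int(matched["treated"].sum()),
               "n_control": int((1 - matched["treated"]).sum()),
               "balance": rep, "adjusted_covariates": adjust,
               "matches": matches}
    results["ir_bp_control"] = {
        int(g): incidence_rate(grp, "patient_months", 100.0)
        for g, grp in bp_rec.groupby("treated")}
    results["ir_mace"] = {
        int(g): incidence_rate(grp, "patient_years", 1000.0)
        for g, grp in mace_rec.groupby("treated")}
    results["hr_bp_control"] = fit_cox(
        bp_rec, adjust_covariates=adjust, endpoint="bp_control")
    ctrl_times = bp_rec.loc[bp_rec["event"] == 1].set_index(
        "patient_id")["time"]
    results["hr_mace"] = fit_cox(
        mace_rec, adjust_covariates=adjust, endpoint="mace",
        time_varying_bp_control=True, bp_control_times=ctrl_times)
    results["km_bp_control"] = km_curve(bp_rec)
    results["km_mace"] = km_curve(mace_rec)
    return results
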