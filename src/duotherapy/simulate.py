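"""Synthetic EHR generator with known ground truth.

Two generation modes:

``generate_population``
    Emits the five raw record streams (patients, prescriptions, BP
    measurements, clinical events; deaths live on the patient table) so
    the whole pipeline — eligibility cascade, episode algebra, matching,
    survival estimation — is exercisable end to end without external
    data. Confounding by indication is injected through covariate
    effects shared by the treatment-assignment (logistic) and outcome
    (proportional-hazards) models, so propensity-score adjustment can in
    principle remove it completely. An optional unmeasured-confounder
    term exists for robustness demonstrations, default off.

``generate_survival_benchmark``
    Bypasses EHR reconstruction: emits covariates, treatment, event and
    censoring times drawn exactly from the configured proportional-
    hazards truth, for estimator-recovery experiments.

Both modes are deterministic given (config, seed): identical inputs
produce byte-identical record streams.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import DRUG_CLASSES, DUO_PAIRS, GeneratorConfig
from .dates import DAYS_PER_MONTH, DAYS_PER_YEAR

__all__ = ["generate_population", "generate_survival_benchmark",
           "draw_covariates", "calibrate_intercept", "BENCHMARK_COVARIATES"]

# Covariate weights in the treatment-assignment logit. Directions mirror the
# observed baseline contrasts: two-drug initiators are younger, more often
# male, heavier, more often current smokers, more severe (grade 3), have a
# longer-standing hypertension diagnosis, more angina/coronary history, far
# more prior antihypertensive use stopped more recently, and fewer GP visits.
_TREAT_W = {
    "z_age": -0.15, "male": 0.15, "smoker": 0.12, "z_bmi": 0.15,
    "grade1": 0.10, "grade3": 0.35, "z_ht_months": 0.45,
    "angina": 0.18, "mi_hist": 0.20, "ckd": -0.10,
    "prior_rx": 1.20, "z_prior_classes": 0.45, "z_months_since_rx": -0.45,
    "z_imd": 0.08, "z_gp_visits": -0.30,
}

# Covariate effects on the BP-control log hazard. Kept modest so the
# marginal and conditional hazard ratios nearly coincide (the hazard ratio
# is non-collapsible; see docs/methods.md).
_BP_W = {
    "grade1": 0.12, "grade3": -0.22, "z_age": 0.06, "z_bmi": -0.10,
    "smoker": -0.06, "diabetes": -0.08, "ckd": -0.08, "prior_rx": -0.10,
    "z_ht_months": -0.08, "z_gp_visits": 0.05,
}

# Covariate effects on the MACE log hazard (classic CV risk factors).
_MACE_W = {
    "z_age": 0.50, "male": 0.25, "mi_hist": 0.70, "angina": 0.40,
    "diabetes": 0.30, "smoker": 0.30, "grade3": 0.30, "ckd": 0.30,
}

#: Covariate columns carried by the direct survival benchmark.
BENCHMARK_COVARIATES = (
    "age", "male", "smoker", "bmi", "imd", "grade1", "grade3", "ht_months",
    "angina", "mi_hist", "diabetes", "ckd", "prior_rx", "n_prior_classes",
    "months_since_rx", "gp_visits",
)

_MONO_PROBS = (0.32, 0.13, 0.27, 0.13, 0.15)  # ACEi, ARB, CCB, TZD, BB
_DUO_PROBS = (0.35, 0.10, 0.08, 0.12, 0.08, 0.04, 0.10, 0.06, 0.07)


def _linpred(z: pd.DataFrame, weights: dict, scale: float,
             u: np.ndarray, u_weight: float) -> np.ndarray:
    lin = np.zeros(len(z))
    for name, w in weights.items():
        lin += w * z[name].to_numpy(dtype=float)
    return scale * lin + u_weight * u


def draw_covariates(rng: np.random.Generator, n: int, config: GeneratorConfig):
    """Draw baseline covariates and the three shared linear predictors.

    Returns ``(cov, lin)`` where ``cov`` is a DataFrame of patient-level
    covariates and ``lin`` a dict with keys ``treat``, ``bp``, ``mace``.
    """
    age = np.clip(np.round(rng.normal(62.0, 14.0, n)), 30, 95)
    male = rng.random(n) < 0.45
    bmi = np.round(np.clip(rng.normal(29.0, 5.8, n), 16, 55), 1)
    smoker = rng.random(n) < 0.19
    imd = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.18, 0.20, 0.20, 0.21, 0.21])
    ethnicity = rng.choice(["white", "other", "missing"], size=n,
                           p=[0.78, 0.05, 0.17])
    diabetes = rng.random(n) < 0.11
    angina = rng.random(n) < 0.075
    mi_hist = rng.random(n) < 0.022
    stroke_hist = rng.random(n) < 0.036
    tia_hist = rng.random(n) < 0.015
    af = rng.random(n) < 0.032
    pad = rng.random(n) < 0.019
    ckd = rng.random(n) < 0.11

    has_ht_dx = rng.random(n) < 0.85
    ht_months = np.where(
        has_ht_dx, np.minimum(np.round(rng.gamma(1.2, 30.0, n), 1), 240.0), 0.0)

    prior_rx = rng.random(n) < 0.74
    months_since_rx = np.where(
        prior_rx, np.round(6.5 + rng.gamma(1.3, 25.0, n), 1), 0.0)
    n_prior_classes = np.where(prior_rx, 1 + rng.poisson(0.8, n), 0)
    gp_visits = rng.poisson(7.8, n)
    hosp_days = np.where(rng.random(n) < 0.15, 1 + rng.poisson(5.0, n), 0)

    # Baseline (pre-index) blood pressure; elevated by cohort definition.
    sbp = np.round(np.clip(rng.normal(164.0, 19.0, n), 126, 260))
    dbp = np.round(np.clip(rng.normal(94.0, 12.0, n), 70, 135))
    not_elevated = (sbp < 140) & (dbp < 90)
    dbp = np.where(not_elevated, 90 + np.abs(np.round(rng.normal(0, 5, n))), dbp)
    dbp = np.minimum(dbp, sbp - 10)
    grade = _bp_grade(sbp, dbp)

    u = rng.normal(0.0, 1.0, n) if config.unmeasured_confounding > 0 else np.zeros(n)

    cov = pd.DataFrame({
        "age": age, "male": male.astype(int), "bmi": bmi,
        "smoker": smoker.astype(int), "imd": imd, "ethnicity": ethnicity,
        "diabetes": diabetes.astype(int), "angina": angina.astype(int),
        "mi_hist": mi_hist.astype(int), "stroke_hist": stroke_hist.astype(int),
        "tia_hist": tia_hist.astype(int), "af": af.astype(int),
        "pad": pad.astype(int), "ckd": ckd.astype(int),
        "has_ht_dx": has_ht_dx.astype(int), "ht_months": ht_months,
        "prior_rx": prior_rx.astype(int), "months_since_rx": months_since_rx,
        "n_prior_classes": n_prior_classes, "gp_visits": gp_visits,
        "hosp_days": hosp_days, "sbp0": sbp, "dbp0": dbp, "grade": grade,
        "grade1": (grade == 1).astype(int), "grade3": (grade == 3).astype(int),
        "u_unmeasured": u,
    })
    return cov, linear_predictors(cov, config)


def linear_predictors(cov: pd.DataFrame, config: GeneratorConfig) -> dict:
    """Shared linear predictors of the assignment and outcome models.

    Recomputable after covariate adjustments so emitted records and the
    generating model stay coherent.
    """
    z = pd.DataFrame({
        "z_age": (cov["age"] - 62.0) / 14.0,
        "male": cov["male"].astype(float), "smoker": cov["smoker"].astype(float),
        "z_bmi": (cov["bmi"] - 29.0) / 5.8,
        "grade1": cov["grade1"].astype(float), "grade3": cov["grade3"].astype(float),
        "z_ht_months": (cov["ht_months"] - 36.0) / 45.0,
        "angina": cov["angina"].astype(float),
        "mi_hist": cov["mi_hist"].astype(float),
        "diabetes": cov["diabetes"].astype(float), "ckd": cov["ckd"].astype(float),
        "prior_rx": cov["prior_rx"].astype(float),
        "z_prior_classes": (cov["n_prior_classes"] - 1.0) / 1.2,
        "z_months_since_rx": np.where(
            cov["prior_rx"] == 1,
            (np.minimum(cov["months_since_rx"], 120.0) - 40.0) / 40.0, 0.0),
        "z_imd": (cov["imd"] - 3.0) / 1.4,
        "z_gp_visits": (cov["gp_visits"] - 7.8) / 3.5,
    })
    s = config.confounding_strength
    uw = config.unmeasured_confounding
    u = cov["u_unmeasured"].to_numpy()
    return {
        "treat": _linpred(z, _TREAT_W, s, u, 0.30 * uw),
        "bp": _linpred(z, _BP_W, s, u, 0.20 * uw),
        "mace": _linpred(z, _MACE_W, s, u, 0.30 * uw),
    }


def _bp_grade(sbp, dbp):
    """Hypertension grade: the max of the systolic and diastolic bands."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    gs = np.select([sbp >= 180, sbp >= 160, sbp >= 140], [3, 2, 1], default=0)
    gd = np.select([dbp >= 110, dbp >= 100, dbp >= 90], [3, 2, 1], default=0)
    return np.maximum(gs, gd)


def calibrate_intercept(lin_treat: np.ndarray, target: float) -> float:
    """Solve the assignment intercept so mean(expit(a + lin)) == target."""

    def f(a):
        return expit(a + lin_treat).mean() - target

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def assign_treatment(rng: np.random.Generator, lin_treat: np.ndarray,
                     target: float):
    alpha = calibrate_intercept(lin_treat, target)
    p = expit(alpha + lin_treat)
    return (rng.random(len(p)) < p).astype(int), alpha, p


# ---------------------------------------------------------------------------
# Direct survival benchmark
# ---------------------------------------------------------------------------

def generate_survival_benchmark(config: GeneratorConfig) -> dict:
    """Analysis-ready cohort drawn exactly from the configured PH truth.

    Returns a dict with keys ``data`` (DataFrame: patient_id, covariates,
    ``treated``, ``time`` in days, ``event``) and ``truth`` (the true
    conditional log-HR, the assignment intercept, and the rates used).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cov, lin = draw_covariates(rng, n, config)
    treated, alpha, ps_true = assign_treatment(
        rng, lin["treat"], config.duo_target_fraction)

    theta = config.true_log_hr_bp_control
    rate_day = (config.benchmark_event_rate / DAYS_PER_MONTH) * np.exp(
        lin["bp"] + theta * treated)
    t_event = rng.exponential(1.0 / rate_day)

    c = np.full(n, np.inf)
    if config.benchmark_censor_rate > 0:
        c = rng.exponential(DAYS_PER_MONTH / config.benchmark_censor_rate, n)
    if config.benchmark_admin_censor_months is not None:
        c = np.minimum(c, config.benchmark_admin_censor_months * DAYS_PER_MONTH)
    event = t_event <= c
    time = np.where(event, t_event, c)

    data = cov[list(BENCHMARK_COVARIATES)].copy()
    data.insert(0, "patient_id", np.arange(n))
    data["treated"] = treated
    data["true_ps"] = ps_true
    data["time"] = np.maximum(time, 1e-3)
    data["event"] = event.astype(int)
    truth = {
        "true_log_hr": theta, "true_hr": math.exp(theta),
        "assignment_intercept": alpha,
        "event_rate_per_month": config.benchmark_event_rate,
        "censor_rate_per_month": config.benchmark_censor_rate,
    }
    return {"data": data, "truth": truth}


# ---------------------------------------------------------------------------
# Full EHR mode
# ---------------------------------------------------------------------------

def _piecewise_exp(rng, h_pre, h_post, t_break):
    """Draw an event time from a hazard that switches at ``t_break`` (days)."""
    e = rng.exponential(1.0)
    if h_pre <= 0 and h_post <= 0:
        return np.inf
    if h_pre > 0 and e < h_pre * t_break:
        return e / h_pre
    if h_post <= 0:
        return np.inf
    used = h_pre * t_break if h_pre > 0 else 0.0
    return t_break + (e - used) / h_post


def _sample_regimen(rng, duo: bool):
    if duo:
        i = rng.choice(len(DUO_PAIRS), p=_DUO_PROBS)
        return set(DUO_PAIRS[i])
    return {rng.choice(DRUG_CLASSES, p=_MONO_PROBS)}


def _simulate_regimen_timeline(rng, config, classes0, t_first_change, fu_cap):
    """Evolve the set of concomitant classes over [0, fu_cap) days.

    Returns a list of (drug_class, start_day, end_day) active intervals.
    The first change arrives at ``t_first_change`` (Weibull-tailed); later
    changes are exponential with the same total hazard. Transition type
    probabilities follow the configured per-transition hazards.
    """
    hz = config.regimen_change_hazards
    rates = np.array([hz["add"], hz["remove"], hz["discontinue"]], dtype=float)
    total = rates.sum()
    p_type = rates / total
    switch_rate = float(hz.get("switch", 0.0))
    classes = set(classes0)
    open_since = {c: 0.0 for c in classes}
    intervals = []
    t = 0.0
    t_next_change = t_first_change

    def _next_switch(now):
        if switch_rate <= 0:
            return np.inf
        return max(now + rng.exponential(DAYS_PER_MONTH / switch_rate), 2.0)

    t_next_switch = _next_switch(0.0)
    for _ in range(12):
        tn = min(t_next_change, t_next_switch)
        if tn >= fu_cap or not classes:
            break
        if t_next_switch < t_next_change:
            # class switch: replace one class, count unchanged
            t = t_next_switch
            absent = [c for c in DRUG_CLASSES if c not in classes]
            if absent:
                old = rng.choice(sorted(classes))
                new = rng.choice(absent)
                intervals.append((old, open_since.pop(old), t))
                classes.discard(old)
                classes.add(new)
                open_since[new] = t
            t_next_switch = _next_switch(t)
            continue
        t = t_next_change
        kind = rng.choice(3, p=p_type)
        if kind == 0 and len(classes) < 4:  # add a class
            absent = [c for c in DRUG_CLASSES if c not in classes]
            new = rng.choice(absent)
            classes.add(new)
            open_since[new] = t
        elif kind == 1:  # remove one class
            drop = rng.choice(sorted(classes))
            intervals.append((drop, open_since.pop(drop), t))
            classes.discard(drop)
        else:  # full discontinuation, possible later restart
            for c in sorted(classes):
                intervals.append((c, open_since.pop(c), t))
            classes.clear()
            if rng.random() < config.p_restart_after_discontinuation:
                t_restart = t + rng.uniform(70, 400)
                if t_restart < fu_cap:
                    new = rng.choice(DRUG_CLASSES, p=_MONO_PROBS)
                    classes = {new}
                    open_since[new] = t_restart
                    t = t_restart
        t_next_change = t + rng.exponential(DAYS_PER_MONTH / total)
        if t_next_switch <= t:
            t_next_switch = _next_switch(t)
    for c, s in open_since.items():
        intervals.append((c, s, fu_cap))
    return [(c, s, e) for c, s, e in intervals if e > s]


def _emit_supplies(rng, config, pid, cls, start, end, fdc_id=None):
    """Refill chain covering [start, end) with jittered gaps."""
    sd = config.supply_days_distribution
    gd = config.refill_gap_distribution
    values = np.asarray(sd["values"])
    probs = np.asarray(sd["probs"])
    rows = []
    s = float(start)
    first = True
    while s < end:
        supply = int(rng.choice(values, p=probs))
        rows.append((pid, cls, int(round(s)), supply,
                     fdc_id if first else None))
        first = False
        if rng.random() < gd["p_long"]:
            gap = rng.uniform(gd["long_min"], gd["long_max"])
        else:
            gap = max(0.0, rng.normal(gd["mean"], gd["sd"]))
        s = s + supply + gap
    return rows


def generate_population(config: GeneratorConfig) -> dict:
    """Generate the five raw record streams plus ground-truth metadata.

    Returns a dict with DataFrames ``patients``, ``prescriptions``,
    ``bp``, ``events`` and a ``truth`` dict. See docs/methods.md for the
    generating model.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cov, _ = draw_covariates(rng, n, config)

    index = rng.integers(config.study_start, config.study_end + 1, n)
    short_hist = rng.random(n) < config.p_short_history
    history = np.where(short_hist, rng.integers(30, 350, n),
                       370 + np.round(rng.exponential(1460, n)).astype(int))
    reg_start = index - history
    reg_end_natural = index + 1 + np.round(rng.exponential(1500, n)).astype(int)

    # Prior antihypertensive use predates the study window (the look-back
    # reaches years before it); chains ending in-window would redefine the
    # first in-window prescription and hence the index. The emitted supply
    # chain therefore ends before the window start, the months-since
    # covariate is recomputed from what is actually on record, and prior
    # use that registration cannot capture is zeroed — keeping the
    # assignment model and the extractable covariates coherent.
    prior_end = np.minimum(
        (index - np.round(cov["months_since_rx"] * DAYS_PER_MONTH)).to_numpy(),
        config.study_start - rng.integers(1, 180, n))
    emittable = (cov["prior_rx"].to_numpy() == 1) & (prior_end - 40 >= reg_start)
    cov.loc[~emittable, ["prior_rx", "months_since_rx", "n_prior_classes"]] = 0
    cov.loc[emittable, "months_since_rx"] = np.round(
        (index[emittable] - prior_end[emittable]) / DAYS_PER_MONTH, 1)
    lin = linear_predictors(cov, config)
    duo, alpha, _ = assign_treatment(rng, lin["treat"], config.duo_target_fraction)

    theta_b = config.true_log_hr_bp_control
    theta_m = config.true_log_hr_mace

    # First regimen change (count-changing transitions only): Weibull with
    # the configured total hazard; the scale is set so the median matches
    # the exponential median ln2/rate.
    hz = config.regimen_change_hazards
    total_rate = hz["add"] + hz["remove"] + hz["discontinue"]  # per month
    k = config.change_time_weibull_shape
    scale_months = (math.log(2) / total_rate) / (math.log(2) ** (1.0 / k))
    # Floor at 2 days: a change on the index day itself would redefine the
    # index regimen.
    t_change = np.maximum(rng.weibull(k, n) * scale_months * DAYS_PER_MONTH, 2.0)

    lam_bp = config.bp_control_rate / DAYS_PER_MONTH
    lam_mi = config.mi_rate / DAYS_PER_MONTH
    lam_st = config.stroke_rate / DAYS_PER_MONTH
    lam_cvd = config.cv_death_rate / DAYS_PER_MONTH
    lam_ncd = config.noncv_death_rate / DAYS_PER_MONTH

    lin_bp = lin["bp"]
    lin_mace = lin["mace"]

    pat_rows, rx_rows, bp_rows, ev_rows = [], [], [], []
    truth_ctrl = np.full(n, np.inf)

    horizon = config.followup_hard_end + 400  # latent times beyond are irrelevant

    secondary = rng.random(n) < config.p_secondary_hypertension
    heart_failure = rng.random(n) < config.p_heart_failure
    recent_prior = rng.random(n) < config.p_recent_prior_rx
    triple = rng.random(n) < config.p_triple_index
    no_recent_bp = rng.random(n) < config.p_no_recent_bp
    mi_recent = rng.random(n) < 0.30  # among those with MI history
    stroke_recent = rng.random(n) < 0.30

    for i in range(n):
        pid = i
        idx = int(index[i])
        rs = int(reg_start[i])
        # -- post-index latent event times (days since index) -----------------
        tb = float(t_change[i])
        if config.equalize_post_change:
            mult_pre_b = math.exp(lin_bp[i] + theta_b * duo[i])
            mult_post_b = math.exp(lin_bp[i] + 0.5 * theta_b)
            mult_pre_m = math.exp(lin_mace[i] + theta_m * duo[i])
            mult_post_m = math.exp(lin_mace[i] + 0.5 * theta_m)
        else:
            mult_pre_b = mult_post_b = math.exp(lin_bp[i] + theta_b * duo[i])
            mult_pre_m = mult_post_m = math.exp(lin_mace[i] + theta_m * duo[i])

        t_ctrl = _piecewise_exp(rng, lam_bp * mult_pre_b, lam_bp * mult_post_b, tb)
        t_mi = _piecewise_exp(rng, lam_mi * mult_pre_m, lam_mi * mult_post_m, tb)
        t_stroke = _piecewise_exp(rng, lam_st * mult_pre_m, lam_st * mult_post_m, tb)
        t_cvd = _piecewise_exp(rng, lam_cvd * mult_pre_m, lam_cvd * mult_post_m, tb)
        t_ncd = rng.exponential(1.0 / (lam_ncd * math.exp(0.5 * (cov["age"].iat[i] - 62) / 14)))

        fatal_mi = rng.random() < config.p_fatal_mi
        fatal_stroke = rng.random() < config.p_fatal_stroke
        death_candidates = [(t_ncd, False)]
        if t_cvd < horizon:
            death_candidates.append((t_cvd, True))
        if t_mi < horizon and fatal_mi:
            death_candidates.append((t_mi + rng.uniform(1, 30), True))
        if t_stroke < horizon and fatal_stroke:
            death_candidates.append((t_stroke + rng.uniform(1, 30), True))
        t_death, death_cv = min(death_candidates, key=lambda x: x[0])

        death_day = idx + int(round(t_death)) if idx + t_death < horizon else None
        reg_end = int(min(reg_end_natural[i],
                          death_day if death_day is not None else reg_end_natural[i]))
        reg_end = max(reg_end, idx + 1)
        # records stop at registration end / death
        rec_end = reg_end

        truth_ctrl[i] = t_ctrl

        pat_rows.append((
            pid, "M" if cov["male"].iat[i] else "F",
            2000 + int(idx // 365.25) - int(cov["age"].iat[i]),
            rs, reg_end, death_day,
            bool(death_cv) if death_day is not None else None,
            cov["bmi"].iat[i], int(cov["smoker"].iat[i]), int(cov["imd"].iat[i]),
            cov["ethnicity"].iat[i],
        ))

        # -- pre-index history events -----------------------------------------
        def ev(day, category, source="primary_care", detail=None, dur=None):
            if rs <= day <= rec_end:
                ev_rows.append((pid, int(day), category, source, detail, dur))

        if cov["has_ht_dx"].iat[i]:
            ev(max(rs, idx - int(round(cov["ht_months"].iat[i] * DAYS_PER_MONTH))),
               "hypertension_dx")
        if secondary[i]:
            ev(idx - rng.integers(30, 1000), "secondary_hypertension")
        if heart_failure[i]:
            ev(idx - rng.integers(30, 2000), "heart_failure", "hospital")
        if cov["mi_hist"].iat[i]:
            back = rng.integers(30, 365) if mi_recent[i] else rng.integers(400, 3000)
            ev(idx - back, "myocardial_infarction", "hospital")
        if cov["stroke_hist"].iat[i]:
            back = rng.integers(30, 365) if stroke_recent[i] else rng.integers(400, 3000)
            ev(idx - back, "stroke", "hospital")
        if cov["tia_hist"].iat[i]:
            ev(idx - rng.integers(30, 2000), "TIA")
        if cov["angina"].iat[i]:
            ev(idx - rng.integers(30, 2000), "angina_ihd")
        if cov["af"].iat[i]:
            ev(idx - rng.integers(30, 2000), "atrial_fibrillation")
        if cov["diabetes"].iat[i]:
            ev(idx - rng.integers(30, 2000), "diabetes")
        if cov["pad"].iat[i]:
            ev(idx - rng.integers(30, 2000), "pad")
        if cov["ckd"].iat[i]:
            ev(idx - rng.integers(30, 2000), "ckd")
        if rng.random() < 0.21:
            ev(idx - rng.integers(1, 365), "comedication_class",
               detail="lipid_lowering")
        if rng.random() < 0.13:
            ev(idx - rng.integers(1, 365), "comedication_class",
               detail="antiplatelet")
        if rng.random() < 0.07:
            ev(idx - rng.integers(1, 365), "comedication_class",
               detail="antidiabetic")
        if cov["hosp_days"].iat[i] > 0:
            ev(idx - rng.integers(1, 365), "other_comorbidity", "hospital",
               dur=int(cov["hosp_days"].iat[i]))
        # GP contacts in the prior year (visit proxy for utilization counts).
        n_gp = int(rng.poisson(max(cov["gp_visits"].iat[i] - 2, 0.5)))
        for _ in range(min(n_gp, 30)):
            ev(idx - rng.integers(1, 365), "other_comorbidity")

        # -- pre-index BP measurements ----------------------------------------
        sbp0, dbp0 = cov["sbp0"].iat[i], cov["dbp0"].iat[i]
        if not no_recent_bp[i]:
            d = idx - rng.integers(0, 92)  # inside the short BP lookback
            if d >= rs:
                bp_rows.append((pid, int(d), sbp0, dbp0))
        for _ in range(1 + rng.poisson(1.5)):
            d = idx - rng.integers(1, 365)
            if d >= rs:
                s_ = max(140, round(sbp0 + rng.normal(0, 8)))
                d_ = min(round(dbp0 + rng.normal(0, 6)), s_ - 10)
                bp_rows.append((pid, int(d), s_, d_))

        # -- prior antihypertensive prescriptions ------------------------------
        if recent_prior[i]:
            # Prevalent user: a refill chain crossing the window boundary, so
            # the first in-window prescription violates the washout and the
            # patient fails new-user status.
            cls = rng.choice(DRUG_CLASSES, p=_MONO_PROBS)
            s_ = config.study_start - 120 - rng.integers(0, 30)
            chain_end = config.study_start + rng.integers(30, 200)
            while s_ < min(chain_end, idx - 1):
                if s_ >= rs:
                    rx_rows.append((pid, cls, int(s_), 28, None))
                s_ += 28 + rng.integers(0, 5)
        elif cov["prior_rx"].iat[i]:
            last_end = int(prior_end[i])
            ncls = int(min(cov["n_prior_classes"].iat[i], 5))
            classes = rng.choice(DRUG_CLASSES, size=ncls, replace=False)
            for cls in classes:
                for j in range(int(rng.integers(1, 4))):
                    s_ = last_end - 28 * (j + 1) - rng.integers(0, 10)
                    if s_ >= rs:
                        rx_rows.append((pid, cls, int(s_), 28, None))

        # -- index regimen and post-index prescriptions ------------------------
        if triple[i]:
            # 3+ classes on the index date: ineligible by design.
            classes0 = set(rng.choice(DRUG_CLASSES, size=3, replace=False))
        else:
            classes0 = _sample_regimen(rng, bool(duo[i]))
        fu_cap = max(min(rec_end, config.followup_hard_end) - idx, 1)
        timeline = _simulate_regimen_timeline(rng, config, classes0,
                                              float(t_change[i]), float(fu_cap))
        fdc = None
        if duo[i] and len(classes0) == 2 and rng.random() < 0.098:
            fdc = f"FDC{pid}"
        for cls, s_, e_ in timeline:
            rows = _emit_supplies(rng, config, pid, cls, idx + s_, idx + e_,
                                  fdc_id=fdc if s_ == 0.0 else None)
            rx_rows.extend(r for r in rows if r[2] < rec_end)

        # -- post-index BP visits ---------------------------------------------
        mean_gap = DAYS_PER_YEAR / config.visit_rate
        t = rng.exponential(mean_gap)
        while idx + t < rec_end and t < fu_cap + 400:
            d = idx + int(round(t))
            if d > idx:
                if t < t_ctrl:
                    s_ = round(rng.normal(max(sbp0 - 8, 146), 9))
                    d_ = round(rng.normal(min(dbp0, 95) - 2, 8))
                    if s_ < 140 and d_ < 90:
                        s_ = 140 + abs(round(rng.normal(0, 6)))
                    d_ = min(d_, s_ - 10)
                else:
                    s_ = round(np.clip(rng.normal(128, 7), 105, 139))
                    d_ = round(np.clip(rng.normal(78, 7), 55, 89))
                bp_rows.append((pid, d, s_, d_))
            t += rng.exponential(mean_gap)

    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "sex", "birth_year", "registration_start",
        "registration_end", "death_date", "death_cause_cv", "bmi", "smoking",
        "deprivation_index", "ethnicity"])
    patients["death_date"] = patients["death_date"].astype("Int64")
    prescriptions = pd.DataFrame(rx_rows, columns=[
        "patient_id", "drug_class", "start_date", "supply_days",
        "fixed_dose_combination_id"])
    prescriptions = prescriptions.sort_values(
        ["patient_id", "start_date", "drug_class"], kind="mergesort",
        ignore_index=True)
    bp = pd.DataFrame(bp_rows, columns=["patient_id", "date", "sbp", "dbp"])
    bp = bp.sort_values(["patient_id", "date"], kind="mergesort",
                        ignore_index=True)
    bp[["sbp", "dbp"]] = bp[["sbp", "dbp"]].astype(int)
    bp["sbp"] = bp["sbp"].clip(60, 280)
    bp["dbp"] = np.minimum(bp["dbp"].clip(30, 180), bp["sbp"] - 1)
    events = pd.DataFrame(ev_rows, columns=[
        "patient_id", "date", "category", "source", "detail", "duration_days"])
    events = events.sort_values(["patient_id", "date", "category"],
                                kind="mergesort", ignore_index=True)

    truth = {
        "true_log_hr_bp_control": theta_b, "true_hr_bp_control": math.exp(theta_b),
        "true_log_hr_mace": theta_m, "true_hr_mace": math.exp(theta_m),
        "assignment_intercept": alpha,
        "duo_fraction_assigned": float(np.mean(duo)),
        "index_dates": pd.DataFrame({"patient_id": np.arange(n),
                                     "index_date_true": index,
                                     "duo_true": duo}),
    }
    return {"patients": patients, "prescriptions": prescriptions, "bp": bp,
            "events": events, "truth": truth}
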