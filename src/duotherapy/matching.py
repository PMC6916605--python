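"""Propensity-score estimation, greedy 1:k caliper matching, and balance.

The propensity score is a maximum-likelihood logistic regression of
two-drug initiation on all baseline covariates. Matching is greedy
nearest-neighbour on the logit scale without replacement, run as
``ratio`` sequential 1:1 passes inside a caliper of
``caliper_multiplier × SD`` of the pooled logits; a treated subject must
secure a control in every pass or is dropped with its controls released.
Balance is summarised by the weighted absolute standardized difference
(ASD), matched controls carrying weight ``1/ratio``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import MatchSpec
from .errors import SeparationError

__all__ = ["PropensityFit", "fit_propensity", "greedy_match",
           "compute_balance", "balance_report", "asd_continuous", "asd_binary"]

_EPS = 1e-12


@dataclass
class PropensityFit:
    covariate_names: list
    coefficients: pd.Series
    score: pd.Series  # indexed by patient_id, in (0, 1)
    logit: pd.Series
    treated: pd.Series  # group indicator, same index
    converged: bool = True
    warnings: list = field(default_factory=list)


def _design_matrix(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix; categoricals expand to indicator columns
    (missing is its own level), so missingness enters the model explicitly."""
    cols = {}
    for c in covariates:
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            s = s.fillna("missing").astype(str)
            levels = sorted(s.unique())
            for lev in levels[1:]:  # first level is the reference
                cols[f"{c}[{lev}]"] = (s == lev).astype(float)
        else:
            cols[c] = s.astype(float).fillna(0.0)
    return pd.DataFrame(cols, index=df.index)


def fit_propensity(df: pd.DataFrame, covariates, group_col: str = "treated",
                   id_col: str = "patient_id") -> PropensityFit:
    """ML logistic fit of the group indicator on baseline covariates.

    Raises :class:`SeparationError` naming the offending covariates when
    the likelihood separates perfectly; collinear (e.g. duplicated)
    columns are handled through the pseudoinverse and reported as a
    warning on the returned fit.
    """
    y = df[group_col].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both groups must be present to fit a propensity score")
    X = _design_matrix(df, covariates)
    constant = X.columns[X.nunique() <= 1]
    X = X.drop(columns=constant)  # no information; would alias the intercept
    fit_warnings = []
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        msg = "collinear covariate columns detected; coefficients not unique"
        warnings.warn(msg, UserWarning, stacklevel=2)
        fit_warnings.append(msg)
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(maxiter=200)
    for w in caught:
        if "separat" in str(w.message).lower():
            fit_warnings.append(str(w.message))
    p = np.clip(np.asarray(res.predict(Xc)), _EPS, 1 - _EPS)
    # Perfect separation: fitted probabilities collapse onto the labels.
    if np.all((p > 1 - 1e-8) == (y == 1)) and np.all((p < 1e-8) == (y == 0)):
        big = res.params.drop("const").abs()
        offenders = list(big[big > 0.5 * big.max()].index)
        raise SeparationError(
            f"perfect separation in propensity model (covariates: {offenders})",
            covariates=offenders)
    idx = (df[id_col] if id_col in df.columns else df.index).to_numpy()
    score = pd.Series(p, index=idx, name="ps")
    return PropensityFit(
        covariate_names=list(X.columns),
        coefficients=res.params,
        score=score,
        logit=pd.Series(np.log(p / (1 - p)), index=idx, name="logit_ps"),
        treated=pd.Series(y.astype(int), index=idx, name="treated"),
        converged=bool(res.converged),
        warnings=fit_warnings,
    )


def _nearest_unused(sorted_logits, used, target, caliper):
    """Index (into the sorted control array) of the nearest unused control
    within the caliper, or -1. Ties (equal distance) go to the lower logit."""
    n = len(sorted_logits)
    j = np.searchsorted(sorted_logits, target)
    left, right = j - 1, j
    while left >= 0 and used[left]:
        left -= 1
    while right < n and used[right]:
        right += 1
    dl = target - sorted_logits[left] if left >= 0 else np.inf
    dr = sorted_logits[right] - target if right < n else np.inf
    while True:
        if dl <= dr:
            if dl > caliper:
                return -1
            return left
        if dr > caliper:
            return -1
        return right


def greedy_match(fit: PropensityFit, spec: MatchSpec) -> pd.DataFrame:
    """Greedy caliper matching without replacement, ``ratio`` passes.

    Returns one row per matched set: ``set_id``, ``treated_id``,
    ``control_ids`` (tuple of length ``ratio``), ``distances`` and the
    realized ``caliper``. Deterministic given the configured seed.
    """
    logit = fit.logit
    treated_mask = fit.treated.to_numpy(dtype=bool)
    t_ids = logit.index.to_numpy()[treated_mask]
    t_log = logit.to_numpy()[treated_mask]
    c_ids = logit.index.to_numpy()[~treated_mask]
    c_log = logit.to_numpy()[~treated_mask]
    if len(t_ids) == 0 or len(c_ids) == 0:
        raise ValueError("cannot match: one of the groups is empty")

    caliper = spec.caliper_multiplier * float(np.std(logit.to_numpy(), ddof=1))

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(t_ids))  # seeded shuffle breaks logit ties
    if spec.order_rule == "logit_desc":
        order = perm[np.argsort(-t_log[perm], kind="stable")]
    elif spec.order_rule == "logit_asc":
        order = perm[np.argsort(t_log[perm], kind="stable")]
    else:  # random
        order = perm

    c_sort = np.argsort(c_log, kind="stable")
    cs_log = c_log[c_sort]
    cs_ids = c_ids[c_sort]
    used = np.zeros(len(cs_log), dtype=bool)

    assigned = {i: [] for i in order}  # treated pos -> list of control slots
    alive = list(order)
    for _pass in range(spec.ratio):
        survivors = []
        for ti in alive:
            j = _nearest_unused(cs_log, used, t_log[ti], caliper)
            if j < 0:
                for slot in assigned[ti]:  # release previously taken controls
                    used[slot] = False
                assigned[ti] = []
            else:
                used[j] = True
                assigned[ti].append(j)
                survivors.append(ti)
        alive = survivors

    rows = []
    for set_id, ti in enumerate(i for i in order if len(assigned[i]) == spec.ratio):
        slots = assigned[ti]
        rows.append({
            "set_id": set_id,
            "treated_id": t_ids[ti],
            "control_ids": tuple(cs_ids[s] for s in slots),
            "distances": tuple(float(abs(cs_log[s] - t_log[ti])) for s in slots),
            "caliper": caliper,
        })
    return pd.DataFrame(rows, columns=["set_id", "treated_id", "control_ids",
                                       "distances", "caliper"])


def matched_long(matches: pd.DataFrame) -> pd.DataFrame:
    """Long form of a match result: one row per (set, patient, role)."""
    rows = []
    for _, r in matches.iterrows():
        rows.append((r["set_id"], r["treated_id"], "treated"))
        for cid in r["control_ids"]:
            rows.append((r["set_id"], cid, "control"))
    return pd.DataFrame(rows, columns=["set_id", "patient_id", "role"])


def asd_continuous(x_t, x_c, w_t=None, w_c=None) -> float:
    """Weighted absolute standardized difference for a continuous covariate:
    |mean_t - mean_c| / sqrt((var_t + var_c) / 2)."""
    m_t, v_t = _wmean_var(x_t, w_t)
    m_c, v_c = _wmean_var(x_c, w_c)
    denom = np.sqrt((v_t + v_c) / 2.0)
    if denom == 0:
        return 0.0 if m_t == m_c else np.inf
    return abs(m_t - m_c) / denom


def asd_binary(p_t: float, p_c: float) -> float:
    """|p_t - p_c| / sqrt((p_t(1-p_t) + p_c(1-p_c)) / 2); 0 when both
    proportions are degenerate and equal."""
    denom = np.sqrt((p_t * (1 - p_t) + p_c * (1 - p_c)) / 2.0)
    if denom == 0:
        return 0.0 if p_t == p_c else np.inf
    return abs(p_t - p_c) / denom


def _wmean_var(x, w):
    x = np.asarray(x, dtype=float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    m = float((w * x).sum() / sw)
    if sw <= 1:
        return m, 0.0
    v = float((w * (x - m) ** 2).sum() / (sw - 1))
    return m, v


def compute_balance(df: pd.DataFrame, covariates, group_col: str = "treated",
                    weight_col: str | None = None) -> pd.DataFrame:
    """Per-covariate weighted ASD for one cohort (matched or unmatched).

    Binary covariates use the proportion formula, continuous ones the
    pooled-variance formula, and categoricals expand to indicator
    columns. Zero variance in both groups yields ASD 0; in one group
    only, the pooled formula applies and the row is flagged.
    """
    w = df[weight_col].to_numpy(float) if weight_col else np.ones(len(df))
    t = df[group_col].astype(bool).to_numpy()
    X = _design_matrix(df, covariates)
    rows = []
    for c in X.columns:
        x = X[c].to_numpy(float)
        values = np.unique(x)
        binary = len(values) <= 2 and set(values) <= {0.0, 1.0}
        if binary:
            p_t = float((w[t] * x[t]).sum() / w[t].sum())
            p_c = float((w[~t] * x[~t]).sum() / w[~t].sum())
            asd = asd_binary(p_t, p_c)
            degenerate = (p_t in (0.0, 1.0)) != (p_c in (0.0, 1.0))
        else:
            m_t, v_t = _wmean_var(x[t], w[t])
            m_c, v_c = _wmean_var(x[~t], w[~t])
            asd = asd_continuous(x[t], x[~t], w[t], w[~t])
            degenerate = (v_t == 0) != (v_c == 0)
        rows.append({"covariate": c,
                     "type": "binary" if binary else "continuous",
                     "asd": asd, "flag_one_group_degenerate": degenerate})
    return pd.DataFrame(rows)


def balance_report(unmatched: pd.DataFrame, matched: pd.DataFrame,
                   covariates, group_col: str = "treated",
                   ratio: int = 2, threshold: float = 0.1) -> pd.DataFrame:
    """Before/after ASD table; matched controls carry weight ``1/ratio``.

    The returned frame has columns ``covariate, type, asd_before,
    asd_after, exceeds_threshold``; rows with ``exceeds_threshold`` feed
    the survival stage's double adjustment.
    """
    before = compute_balance(unmatched, covariates, group_col)
    m = matched.copy()
    m["_w"] = np.where(m[group_col].astype(bool), 1.0, 1.0 / ratio)
    after = compute_balance(m, covariates, group_col, weight_col="_w")
    rep = before[["covariate", "type", "asd"]].rename(columns={"asd": "asd_before"})
    rep = rep.merge(after[["covariate", "asd"]].rename(columns={"asd": "asd_after"}),
                    on="covariate")
    rep["exceeds_threshold"] = rep["asd_after"] > threshold
    return rep
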