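"""Treatment-episode algebra and as-treated / ITT exposure.

Prescriptions become per-class episodes (supplies merged when they
overlap or when the gap from one supply's end to the next start is
strictly below the discontinuation threshold). Episodes of different
classes overlapping at least the concomitancy threshold create
multi-class regimen spells; shorter overlaps are class switches, with
the outgoing class truncated at the incoming class's start. The first
boundary at which the number of concomitant classes changes defines the
as-treated end and the regimen-change type.

All intervals are half-open ``[start, end)`` day intervals. The rules
and the tie-break decisions (same-day starts, nested short episodes,
interior bridged gaps, terminal discontinuation) are documented in
docs/methods.md; the test suite checks them against an independent
day-grid implementation.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import EpisodeConfig
from .errors import ContractViolation

logger = logging.getLogger(__name__)

__all__ = ["build_class_episodes", "segment_regimens", "classify_first_change",
           "define_followup", "build_exposure", "CHANGE_TYPES"]

CHANGE_TYPES = ("none_persistence", "none_class_switch", "add_class",
                "remove_class_to_fewer", "full_discontinuation",
                "switch_to_monotherapy")


def build_class_episodes(prescriptions: pd.DataFrame,
                         config: EpisodeConfig) -> pd.DataFrame:
    """Merge per-class supply intervals into continuous-use episodes.

    Supplies of the same patient and class merge when they overlap or
    when ``next.start - current.end < discontinuation_gap_days`` (strict:
    a gap of exactly the threshold separates episodes). The episode end
    is the latest covered supply end. Rows with nonpositive supply are
    rejected and logged.
    """
    rx = prescriptions.copy()
    bad = rx["supply_days"] < 1
    if bad.any():
        logger.warning("rejecting %d prescriptions with nonpositive supply",
                       int(bad.sum()))
        rx = rx[~bad]
    if rx.empty:
        return pd.DataFrame(columns=["patient_id", "drug_class", "start", "end"])
    rx = rx.sort_values(["patient_id", "drug_class", "start_date"],
                        kind="mergesort")
    rx["supply_end"] = rx["start_date"] + rx["supply_days"]
    g = rx.groupby(["patient_id", "drug_class"], sort=True)
    running_end = g["supply_end"].cummax()
    prev_end = running_end.groupby(
        [rx["patient_id"], rx["drug_class"]]).shift(1)
    new_episode = prev_end.isna() | (
        rx["start_date"] - prev_end >= config.discontinuation_gap_days)
    rx["episode_id"] = new_episode.cumsum()
    episodes = (rx.groupby(["patient_id", "drug_class", "episode_id"], sort=True)
                .agg(start=("start_date", "min"), end=("supply_end", "max"))
                .reset_index().drop(columns="episode_id"))
    return episodes.sort_values(["patient_id", "start", "drug_class"],
                                kind="mergesort", ignore_index=True)


def _resolve_overlaps(eps: list, min_overlap: int) -> list:
    """Resolve sub-threshold overlaps between classes for one patient.

    ``eps`` is a list of ``[drug_class, start, end]``. Repeatedly find
    the earliest violating pair — ordered by incoming start, then
    outgoing start, then class names — and apply the switch-truncation
    rule: hand-off (earlier episode ends no later than the incoming one)
    truncates the outgoing episode at the incoming start; a short episode
    nested inside another class's episode is dropped. Episodes starting
    the same day are never truncated against each other (a genuine
    same-day combination regimen).
    """
    eps = [list(e) for e in eps]
    while True:
        eps.sort(key=lambda e: (e[1], e[2], e[0]))
        violation = None
        for j in range(len(eps)):
            for i in range(len(eps)):
                if i == j or eps[i][0] == eps[j][0]:
                    continue
                a, b = eps[i], eps[j]
                if not (a[1] < b[1]):  # b must start strictly after a
                    continue
                overlap = min(a[2], b[2]) - b[1]
                if 0 < overlap < min_overlap:
                    key = (b[1], a[1], b[0], a[0])
                    if violation is None or key < violation[0]:
                        violation = (key, i, j)
            # keep scanning: earliest pair selected by key ordering
        if violation is None:
            return [tuple(e) for e in eps if e[2] > e[1]]
        _, i, j = violation
        a, b = eps[i], eps[j]
        if a[2] <= b[2]:
            a[2] = b[1]  # hand-off: truncate outgoing at incoming start
        else:
            b[2] = b[1]  # nested short episode: drop
        eps = [e for e in eps if e[2] > e[1]]


def segment_regimens(episodes: pd.DataFrame,
                     config: EpisodeConfig) -> pd.DataFrame:
    """Partition each patient's treated time into constant-regimen spells.

    Returns columns ``patient_id, start, end, classes`` where ``classes``
    is a sorted tuple of active drug classes. Spells are disjoint,
    ordered, and adjacent spells differ in membership; zero-class gaps
    are not emitted as spells.
    """
    rows = []
    for pid, grp in episodes.groupby("patient_id", sort=True):
        eps = _resolve_overlaps(
            grp[["drug_class", "start", "end"]].values.tolist(),
            config.min_concomitant_overlap_days)
        if not eps:
            continue
        bounds = sorted({e[1] for e in eps} | {e[2] for e in eps})
        pending = None
        for s, e in zip(bounds[:-1], bounds[1:]):
            active = tuple(sorted(c for c, cs, ce in eps if cs <= s and e <= ce))
            if not active:
                if pending is not None:
                    rows.append(pending)
                    pending = None
                continue
            if pending is not None and pending[3] == active and pending[2] == s:
                pending = (pid, pending[1], e, active)
            else:
                if pending is not None:
                    rows.append(pending)
                pending = (pid, s, e, active)
        if pending is not None:
            rows.append(pending)
    return pd.DataFrame(rows, columns=["patient_id", "start", "end", "classes"])


def classify_first_change(spells: pd.DataFrame, entry, config: EpisodeConfig):
    """Classify the first regimen change for one cohort entry.

    ``entry`` needs ``patient_id``, ``index_date``, ``initial_classes``
    and ``admin_end`` (min of registration end, death and the hard
    follow-up end). Spells must begin at the index date with the index
    regimen, else :class:`ContractViolation` is raised.

    A regimen change is a change in the *number* of concomitant classes;
    same-count membership changes are class switches and do not end
    as-treated time. Gaps between spells shorter than the
    discontinuation threshold are bridged; a gap at least the threshold
    (including the terminal gap before ``admin_end``) is a full
    discontinuation dated at the last supply end.
    """
    gap_days = config.discontinuation_gap_days
    if isinstance(spells, pd.DataFrame):
        sp = spells[spells["patient_id"] == entry["patient_id"]] \
            if "patient_id" in spells.columns else spells
        sp = sp.sort_values("start")
        spell_list = list(zip(sp["start"], sp["end"], sp["classes"]))
    else:
        spell_list = sorted(spells)
    if not spell_list:
        raise ContractViolation(f"no spells for patient {entry['patient_id']}")
    s0, e0, c0 = spell_list[0]
    init = tuple(sorted(entry["initial_classes"]))
    if s0 != entry["index_date"] or tuple(c0) != init:
        raise ContractViolation(
            f"spells for patient {entry['patient_id']} do not begin at the "
            f"index date with the index regimen")
    admin_end = entry["admin_end"]
    base_count = len(init)
    had_switch = False

    def _done(change_type, change_date, as_treated_end):
        return {"patient_id": entry["patient_id"], "change_type": change_type,
                "change_date": change_date, "as_treated_end": as_treated_end}

    def _decrease_type(n_new):
        if base_count == 2 and n_new == 1:
            return "switch_to_monotherapy"
        return "remove_class_to_fewer"

    prev_end, prev_classes = e0, c0
    for start, end, classes in spell_list[1:]:
        if start - prev_end >= gap_days:
            return _done("full_discontinuation", prev_end, prev_end)
        n_prev, n_next = len(prev_classes), len(classes)
        if n_next > n_prev:
            return _done("add_class", start, start)
        if n_next < n_prev:
            return _done(_decrease_type(n_next), prev_end, prev_end)
        had_switch = True  # same count, different membership
        prev_end, prev_classes = end, classes

    if admin_end - prev_end >= gap_days:
        return _done("full_discontinuation", prev_end, prev_end)
    # Exposure deemed ongoing: no confirmable terminal gap before data end.
    change_type = "none_class_switch" if had_switch else "none_persistence"
    return _done(change_type, None, admin_end)


def define_followup(cohort: pd.DataFrame, change_records: pd.DataFrame,
                    patients: pd.DataFrame, mode: str,
                    config, hard_end: int) -> pd.DataFrame:
    """Follow-up interval per patient under as-treated or ITT exposure.

    As-treated follow-up ends at ``min(as_treated_end, administrative
    ends)``; ITT ignores the regimen change entirely. Administrative ends
    are registration end, death and the coverage hard end. The censoring
    reason labels whichever bound was reached.
    """
    if mode not in ("as_treated", "itt"):
        raise ValueError(f"unknown mode {mode!r}")
    p = patients.set_index("patient_id")
    out = cohort[["patient_id", "index_date"]].copy()
    reg_end = p["registration_end"].reindex(out["patient_id"]).to_numpy()
    death = p["death_date"].reindex(out["patient_id"]).to_numpy(dtype="float")
    death = np.where(np.isnan(death), np.inf, death)
    admin = np.minimum(np.minimum(reg_end, death), hard_end)

    cr = change_records.set_index("patient_id")
    at_end = cr["as_treated_end"].reindex(out["patient_id"]).to_numpy(dtype="float")
    if mode == "as_treated":
        end = np.minimum(admin, at_end)
    else:
        end = admin
    end = np.maximum(end, out["index_date"].to_numpy() + 1)

    reason = np.select(
        [end == death, (mode == "as_treated") & (end == at_end) & (at_end < admin),
         end == hard_end, end == reg_end],
        ["death", "regimen_change", "coverage_end", "registration_end"],
        default="administrative")
    out["followup_end"] = end.astype(int)
    out["censor_reason"] = reason
    return out


def build_exposure(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                   patients: pd.DataFrame, config: EpisodeConfig,
                   hard_end: int, mode: str = "as_treated") -> dict:
    """Full exposure stage for a cohort: episodes, spells, change, follow-up.

    Prescriptions before the index date are ignored (pre-washout use is
    a baseline covariate, not exposure). Returns a dict with the
    ``episodes``, ``spells``, ``changes`` and ``followup`` tables.
    """
    p = patients.set_index("patient_id")
    idx = cohort.set_index("patient_id")["index_date"]
    rx = prescriptions[prescriptions["patient_id"].isin(idx.index)].copy()
    rx = rx[rx["start_date"] >= rx["patient_id"].map(idx)]
    episodes = build_class_episodes(rx, config)
    spells = segment_regimens(episodes, config)

    death = p["death_date"]
    reg_end = p["registration_end"]
    init_classes = cohort.set_index("patient_id")["initial_classes"]
    changes = []
    spell_lists = {
        pid: list(zip(grp["start"], grp["end"], grp["classes"]))
        for pid, grp in spells.groupby("patient_id", sort=True)}
    for pid, spell_list in spell_lists.items():
        d = death.get(pid)
        admin_end = min(reg_end.at[pid],
                        hard_end if pd.isna(d) else min(hard_end, int(d)))
        entry = {"patient_id": pid, "index_date": int(idx[pid]),
                 "initial_classes": init_classes.at[pid],
                 "admin_end": int(admin_end)}
        changes.append(classify_first_change(spell_list, entry, config))
    changes = pd.DataFrame(changes)
    followup = define_followup(cohort, changes, patients, mode, config, hard_end)
    return {"episodes": episodes, "spells": spells, "changes": changes,
            "followup": followup}
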