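"""Glue for comparing the interval implementation against the day-grid
oracle on randomly generated prescription histories."""
from __future__ import annotations

import numpy as np
import pandas as pd

import _daygrid
from duotherapy.config import DRUG_CLASSES
from duotherapy.episodes import (build_class_episodes, classify_first_change,
                                 segment_regimens)


def random_patient(rng, pid=0):
    """A random prescription history starting at a shared index day.

    1-3 classes start on day 1000 (the index); each class gets 1-8
    further supplies with jittered gaps so that merges, splits, short
    and long overlaps, switches and terminal gaps all occur.
    """
    n_classes = rng.integers(1, 4)
    classes = list(rng.choice(DRUG_CLASSES, size=n_classes, replace=False))
    index = 1000
    supplies = []
    for j, cls in enumerate(classes):
        start = index if j < max(1, n_classes - 1) or rng.random() < 0.7 \
            else index + int(rng.integers(1, 150))
        t = start
        for _ in range(int(rng.integers(1, 9))):
            supply = int(rng.integers(7, 91))
            supplies.append((cls, t, supply))
            t += supply + int(rng.integers(0, 90))
        if rng.random() < 0.3:  # occasional late extra class episode
            extra = int(rng.integers(100, 500))
            supplies.append((cls, index + extra, int(rng.integers(7, 91))))
    initial = sorted({cls for cls, s, _ in supplies if s == index})
    if not initial:  # ensure the index day is supplied
        supplies.append((classes[0], index, 28))
        initial = [classes[0]]
    admin_end = index + int(rng.integers(200, 1200))
    supplies = [(c, s, d) for c, s, d in supplies if s < admin_end]
    supplies = [(c, s, d) for c, s, d in supplies
                if s == index or s > index]  # no pre-index history here
    return {"patient_id": pid, "index_date": index,
            "initial_classes": tuple(initial), "admin_end": admin_end,
            "supplies": supplies}


def interval_exposure(patient, config):
    rx = pd.DataFrame(
        [(patient["patient_id"], c, s, d) for c, s, d in patient["supplies"]],
        columns=["patient_id", "drug_class", "start_date", "supply_days"])
    episodes = build_class_episodes(rx, config)
    spells = segment_regimens(episodes, config)
    change = classify_first_change(
        list(zip(spells["start"], spells["end"], spells["classes"])),
        patient, config)
    ep = {cls: sorted(zip(g["start"], g["end"]))
          for cls, g in episodes.groupby("drug_class")}
    sp = list(zip(spells["start"], spells["end"], spells["classes"]))
    return ep, sp, (change["change_type"], change["change_date"])


def grid_exposure(patient, config):
    eps = _daygrid.grid_episodes(patient["supplies"],
                                 config.discontinuation_gap_days)
    resolved = _daygrid.grid_resolve_overlaps(
        eps, config.min_concomitant_overlap_days)
    spells = _daygrid.grid_spells(resolved)
    change = _daygrid.grid_first_change(
        spells, patient["index_date"], patient["initial_classes"],
        patient["admin_end"], config.discontinuation_gap_days)
    ep = {cls: sorted(e) for cls, e in eps.items()}
    return ep, spells, change


def assert_patient_agreement(patient, config):
    ep_i, sp_i, ch_i = interval_exposure(patient, config)
    ep_g, sp_g, ch_g = grid_exposure(patient, config)
    assert ep_i == ep_g, f"episodes differ for {patient}"
    assert sp_i == sp_g, f"spells differ for {patient}"
    assert ch_i == ch_g, f"change differs for {patient}: {ch_i} vs {ch_g}"
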