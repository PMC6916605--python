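"""Brute-force day-grid reference implementation of the exposure rules.

Works on explicit per-day arrays instead of interval arithmetic: mark
supplied days, close sub-threshold gaps, read off episodes, resolve
sub-threshold between-class overlaps on the day grid, recompute class
counts daily, and classify the first regimen change by walking runs of
constant daily class sets. Used only as an independent oracle for the
interval implementation.
"""
from __future__ import annotations

import numpy as np


def grid_episodes(supplies, gap_days):
    """Episodes per class from (cls, start, supply_days) triples.

    Marks every supplied day, then splits the sorted day sequence where
    the jump between consecutive supplied days exceeds ``gap_days``
    (a jump of d days means d-1 unsupplied days in between, and the
    merge rule bridges strictly fewer than ``gap_days`` of them).
    Returns {cls: [(start, end), ...]} with half-open intervals.
    """
    by_class = {}
    for cls, start, supply in supplies:
        if supply < 1:
            continue
        by_class.setdefault(cls, set()).update(range(start, start + supply))
    episodes = {}
    for cls, days in by_class.items():
        days = np.array(sorted(days))
        breaks = np.where(np.diff(days) > gap_days)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(days) - 1]])
        episodes[cls] = [(int(days[a]), int(days[b]) + 1)
                        for a, b in zip(starts, ends)]
    return episodes


def _flatten(episodes):
    out = []
    for cls, eps in episodes.items():
        for s, e in eps:
            out.append([cls, s, e])
    return out


def grid_resolve_overlaps(episodes, min_overlap):
    """Sub-threshold overlap resolution replayed on day sets.

    The earliest violating ordered pair — (incoming start, outgoing
    start, incoming class, outgoing class) — is resolved one at a time:
    a hand-off removes the outgoing episode's days from the incoming
    start onward; a nested short episode loses all its days. Equal-start
    episodes are never resolved against each other.
    """
    eps = [[cls, set(range(s, e))] for cls, s, e in _flatten(episodes)]
    while True:
        violation = None
        for a in eps:
            for b in eps:
                if a is b or a[0] == b[0] or not a[1] or not b[1]:
                    continue
                a_start, b_start = min(a[1]), min(b[1])
                if not a_start < b_start:
                    continue
                shared = a[1] & b[1]
                if 0 < len(shared) < min_overlap:
                    key = (b_start, a_start, b[0], a[0])
                    if violation is None or key < violation[0]:
                        violation = (key, a, b)
        if violation is None:
            break
        _, a, b = violation
        a_end, b_end = max(a[1]) + 1, max(b[1]) + 1
        if a_end <= b_end:
            a[1] = {d for d in a[1] if d < min(b[1])}
        else:
            b[1] = set()
    return [(cls, days) for cls, days in eps if days]


def grid_spells(resolved):
    """Runs of constant nonempty daily class sets → spells."""
    day_classes = {}
    for cls, days in resolved:
        for d in days:
            day_classes.setdefault(d, set()).add(cls)
    if not day_classes:
        return []
    spells = []
    current, start, prev = None, None, None
    for d in sorted(day_classes):
        s = frozenset(day_classes[d])
        if current is not None and s == current and d == prev + 1:
            prev = d
            continue
        if current is not None:
            spells.append((start, prev + 1, tuple(sorted(current))))
        current, start, prev = s, d, d
    spells.append((start, prev + 1, tuple(sorted(current))))
    return spells


def grid_first_change(spells, index_date, initial_classes, admin_end,
                      gap_days):
    """First-regimen-change classification on day-grid spells.

    Mirrors the documented semantics: bridge between-spell gaps shorter
    than ``gap_days``, count-increase dates at the incoming spell start,
    count-decrease dates at the outgoing spell end, terminal
    discontinuation only when a full gap is observable before
    ``admin_end``.
    """
    assert spells and spells[0][0] == index_date
    assert spells[0][2] == tuple(sorted(initial_classes))
    base = len(initial_classes)
    switched = False
    prev_end, prev_n = spells[0][1], len(spells[0][2])
    for start, end, classes in spells[1:]:
        if start - prev_end >= gap_days:
            return "full_discontinuation", prev_end
        n = len(classes)
        if n > prev_n:
            return "add_class", start
        if n < prev_n:
            if base == 2 and n == 1:
                return "switch_to_monotherapy", prev_end
            return "remove_class_to_fewer", prev_end
        switched = True
        prev_end, prev_n = end, n
    if admin_end - prev_end >= gap_days:
        return "full_discontinuation", prev_end
    return ("none_class_switch" if switched else "none_persistence"), None
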