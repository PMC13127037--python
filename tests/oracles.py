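"""Independent brute-force day-grid oracles.

Every oracle works by explicitly painting days onto a grid (Python sets)
and re-deriving the quantity by enumeration, sharing no code with the
interval-sweep implementations it checks.  Intended for small day ranges
only.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd


def _runs(days: set[int]) -> list[tuple[int, int]]:
    """Maximal consecutive runs of a day set, sorted."""
    out = []
    for d in sorted(days):
        if out and d == out[-1][1] + 1:
            out[-1] = (out[-1][0], d)
        else:
            out.append((d, d))
    return out


def grid_merge(records: pd.DataFrame, gap_days: int = 60) -> dict:
    """Gap-merged episodes per (patient, drug), by painting and dilating.

    Returns {(patient_id, drug_name): [(start, end), ...]}.
    """
    out = {}
    for (pid, drug), grp in records.groupby(["patient_id", "drug_name"]):
        days = set()
        for s, e in zip(grp["start_day"], grp["end_day"]):
            days.update(range(int(s), int(e) + 1))
        runs = _runs(days)
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] < gap_days:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        out[(pid, drug)] = merged
    return out


def grid_filter(intervals: list[tuple[int, int]], min_days: int = 14) -> list[tuple[int, int]]:
    return [(s, e) for s, e in intervals if e - s + 1 >= min_days]


def _active_drugs(episodes: pd.DataFrame, day: int) -> set:
    return set(episodes.loc[(episodes["start"] <= day) & (episodes["end"] >= day), "drug_name"])


def grid_concurrency(episodes: pd.DataFrame, day: int) -> int:
    """Distinct drugs active on a given day, counted directly."""
    return len(_active_drugs(episodes, day))


def grid_max_concurrency(episodes: pd.DataFrame, window: tuple[int, int]) -> int:
    return max(
        (grid_concurrency(episodes, d) for d in range(window[0], window[1] + 1)),
        default=0,
    )


def grid_polypharmacy(
    episodes: pd.DataFrame, window: tuple[int, int], min_overlap_days: int = 14
) -> bool:
    """True iff some drug pair is co-active on ≥ min_overlap_days window days."""
    win = range(window[0], window[1] + 1)
    days_by_drug = {}
    for drug, grp in episodes.groupby("drug_name"):
        days = set()
        for s, e in zip(grp["start"], grp["end"]):
            days.update(d for d in win if s <= d <= e)
        days_by_drug[drug] = days
    return any(
        len(days_by_drug[a] & days_by_drug[b]) >= min_overlap_days
        for a, b in combinations(days_by_drug, 2)
    )


def grid_pair_counts(episodes_by_patient: dict, window_by_patient: dict, min_overlap_days: int = 14) -> dict:
    """Brute-force patient counts per unordered drug pair."""
    counts: dict[tuple[str, str], int] = {}
    for pid, eps in episodes_by_patient.items():
        win = window_by_patient[pid]
        win_range = range(win[0], win[1] + 1)
        days_by_drug = {}
        for drug, grp in eps.groupby("drug_name"):
            days = set()
            for s, e in zip(grp["start"], grp["end"]):
                days.update(d for d in win_range if s <= d <= e)
            days_by_drug[drug] = days
        for a, b in combinations(sorted(days_by_drug), 2):
            if len(days_by_drug[a] & days_by_drug[b]) >= min_overlap_days:
                counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def grid_states(episodes: pd.DataFrame, window: tuple[int, int]) -> list[tuple[frozenset, int, int]]:
    """Per-day active class sets grouped into maximal constant runs."""
    sets_by_day = []
    for d in range(window[0], window[1] + 1):
        active = frozenset(
            episodes.loc[(episodes["start"] <= d) & (episodes["end"] >= d), "med_class"]
        )
        sets_by_day.append((d, active))
    out: list[tuple[frozenset, int, int]] = []
    for d, s in sets_by_day:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1], d)
        else:
            out.append((s, d, d))
    return out


def grid_class_coverage(episodes: pd.DataFrame, med_class: str, window: tuple[int, int]) -> int:
    """Window days covered by ≥1 episode of the class, counted directly."""
    cls = episodes[episodes["med_class"] == med_class]
    days = set()
    for s, e in zip(cls["start"], cls["end"]):
        days.update(d for d in range(window[0], window[1] + 1) if s <= d <= e)
    return len(days)
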