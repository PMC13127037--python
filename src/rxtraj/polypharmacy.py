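"""Polypharmacy ascertainment over merged treatment episodes.

Polypharmacy within an assessment window is defined at the *drug* level:
it is present when at least two distinct drugs have episodes whose mutual
overlap inside the window totals at least ``min_overlap_days`` (default
14).  The 14-day overlap requirement protects against counting a clean
switch (stop one drug, start another) as concurrent treatment.  The
number of unique medications is the maximum number of distinct drugs
simultaneously active on any day of the window, computed by a sweep over
episode endpoints.

Checkpoint assessments follow the cohort's anchor: baseline uses the
±14-day index window, later checkpoints (10 weeks, 6/12/18 months) use a
±35-day window around the checkpoint day.  Denominators at each
checkpoint are the *qualifying* patients — those with at least one active
episode in the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import percentage, wald_proportion_ci

DEFAULT_MIN_OVERLAP_DAYS = 14

#: checkpoint anchor days relative to index; baseline handled separately
DEFAULT_CHECKPOINTS: dict[str, int] = {
    "baseline": 0,
    "10_weeks": 70,
    "6_months": 182,
    "12_months": 365,
    "18_months": 548,
}
DEFAULT_CHECKPOINT_HALFWIDTH = 35

MULTIDRUG_BINS = ("1", "2", "3", "4", ">4")


@dataclass(frozen=True)
class ConcurrencyTimeline:
    """Step function of simultaneously active distinct drugs.

    ``breakpoints`` has one more entry than ``counts``; counts[i] applies
    on days breakpoints[i] .. breakpoints[i+1]−1 inclusive.
    """

    patient_id: object
    breakpoints: np.ndarray
    counts: np.ndarray

    def count_on(self, day: int) -> int:
        if len(self.counts) == 0 or day < self.breakpoints[0] or day >= self.breakpoints[-1]:
            return 0
        i = int(np.searchsorted(self.breakpoints, day, side="right")) - 1
        return int(self.counts[i])

    def max_in(self, start: int, end: int) -> int:
        """Maximum count over days start..end (closed)."""
        if len(self.counts) == 0:
            return 0
        lo = int(np.searchsorted(self.breakpoints, start, side="right")) - 1
        hi = int(np.searchsorted(self.breakpoints, end, side="right")) - 1
        lo = max(lo, 0)
        hi = min(hi, len(self.counts) - 1)
        if hi < lo:
            return 0
        return int(self.counts[lo:hi + 1].max())


@dataclass(frozen=True)
class WindowAssessment:
    patient_id: object
    window: tuple[int, int]
    n_unique_max: int
    polypharmacy: bool
    qualifying: bool


def concurrency_timeline(episodes: pd.DataFrame) -> ConcurrencyTimeline:
    """Sweep-line timeline of distinct active drugs for one patient.

    Episodes must already be gap-merged, so episodes of the same drug are
    disjoint and the number of active episodes equals the number of
    distinct active drugs on every day.
    """
    pids = episodes["patient_id"].unique() if not episodes.empty else []
    if len(pids) > 1:
        raise ValueError("concurrency_timeline expects episodes of a single patient")
    pid = pids[0] if len(pids) else None
    if episodes.empty:
        return ConcurrencyTimeline(pid, np.array([], dtype=int), np.array([], dtype=int))
    # +1 at start, −1 the day after end (closed intervals)
    deltas: dict[int, int] = {}
    for s, e in zip(episodes["start"], episodes["end"]):
        deltas[int(s)] = deltas.get(int(s), 0) + 1
        deltas[int(e) + 1] = deltas.get(int(e) + 1, 0) - 1
    days = np.array(sorted(deltas), dtype=int)
    counts = np.cumsum([deltas[d] for d in days])[:-1]
    return ConcurrencyTimeline(pid, days, counts.astype(int))


def _pair_overlap_days(eps_a: pd.DataFrame, eps_b: pd.DataFrame, window: tuple[int, int]) -> int:
    """Total days inside `window` on which drugs a and b are both active."""
    w0, w1 = window
    total = 0
    for sa, ea in zip(eps_a["start"], eps_a["end"]):
        for sb, eb in zip(eps_b["start"], eps_b["end"]):
            lo = max(sa, sb, w0)
            hi = min(ea, eb, w1)
            if hi >= lo:
                total += hi - lo + 1
    return total


def assess_window(
    episodes: pd.DataFrame,
    window: tuple[int, int],
    min_overlap_days: int = DEFAULT_MIN_OVERLAP_DAYS,
    timeline: ConcurrencyTimeline | None = None,
) -> WindowAssessment:
    """Polypharmacy assessment for one patient over a closed window."""
    w0, w1 = window
    if w1 < w0:
        raise ValueError("window end before start")
    pid = episodes["patient_id"].iloc[0] if not episodes.empty else None
    in_win = episodes[(episodes["start"] <= w1) & (episodes["end"] >= w0)] if not episodes.empty else episodes
    if in_win.empty:
        return WindowAssessment(pid, window, 0, False, False)

    if timeline is None:
        timeline = concurrency_timeline(episodes)
    n_unique_max = timeline.max_in(w0, w1)

    poly = False
    by_drug = dict(tuple(in_win.groupby("drug_name")))
    for a, b in combinations(sorted(by_drug), 2):
        if _pair_overlap_days(by_drug[a], by_drug[b], window) >= min_overlap_days:
            poly = True
            break
    return WindowAssessment(pid, window, n_unique_max, poly, True)


def assess_cohort_window(
    episodes: pd.DataFrame,
    cohort: pd.DataFrame,
    window_offsets: tuple[int, int],
    min_overlap_days: int = DEFAULT_MIN_OVERLAP_DAYS,
) -> pd.DataFrame:
    """assess_window for every cohort patient, window relative to index.

    Returns a DataFrame (patient_id, n_unique_max, polypharmacy,
    qualifying).
    """
    ep_by_pt = dict(tuple(episodes.groupby("patient_id"))) if not episodes.empty else {}
    empty = episodes.iloc[0:0]
    rows = []
    for pid, index_day in zip(cohort["patient_id"], cohort["index_date"]):
        eps = ep_by_pt.get(pid, empty)
        win = (int(index_day) + window_offsets[0], int(index_day) + window_offsets[1])
        a = assess_window(eps, win, min_overlap_days)
        rows.append((pid, a.n_unique_max, a.polypharmacy, a.qualifying))
    return pd.DataFrame(rows, columns=["patient_id", "n_unique_max", "polypharmacy", "qualifying"])


def checkpoint_windows(
    baseline_halfwidth: int = 14,
    checkpoints: dict[str, int] | None = None,
    halfwidth: int = DEFAULT_CHECKPOINT_HALFWIDTH,
) -> dict[str, tuple[int, int]]:
    """Index-relative assessment windows for each checkpoint."""
    checkpoints = checkpoints or DEFAULT_CHECKPOINTS
    wins = {}
    for name, t in checkpoints.items():
        if name == "baseline":
            wins[name] = (-baseline_halfwidth, baseline_halfwidth)
        else:
            wins[name] = (t - halfwidth, t + halfwidth)
    return wins


def checkpoint_table(
    episodes: pd.DataFrame,
    cohort: pd.DataFrame,
    windows: dict[str, tuple[int, int]] | None = None,
    min_overlap_days: int = DEFAULT_MIN_OVERLAP_DAYS,
) -> pd.DataFrame:
    """Distribution of unique-medication counts per checkpoint.

    For each checkpoint: qualifying-patient counts in bins {1,2,3,4,>4}
    of the maximum concurrent unique medications, and the proportion with
    >1 medication with a Wald 95% CI.  Percentages rounded half-up to one
    decimal; a checkpoint with no qualifying patient yields n=0 rows with
    missing proportions.
    """
    windows = windows or checkpoint_windows()
    rows = []
    for name, win in windows.items():
        ass = assess_cohort_window(episodes, cohort, win, min_overlap_days)
        q = ass[ass["qualifying"]]
        n_q = len(q)
        bin_counts = {
            "1": int((q["n_unique_max"] == 1).sum()),
            "2": int((q["n_unique_max"] == 2).sum()),
            "3": int((q["n_unique_max"] == 3).sum()),
            "4": int((q["n_unique_max"] == 4).sum()),
            ">4": int((q["n_unique_max"] > 4).sum()),
        }
        k_multi = int(q["polypharmacy"].sum())
        if n_q:
            ci = wald_proportion_ci(k_multi, n_q)
            pct, lo, hi = ci.display
        else:
            pct = lo = hi = float("nan")
        row = {"checkpoint": name, "n_qualifying": n_q}
        for b in MULTIDRUG_BINS:
            row[f"n_{b}"] = bin_counts[b]
            row[f"pct_{b}"] = percentage(bin_counts[b], n_q) if n_q else float("nan")
        row.update({"n_multi": k_multi, "pct_multi": pct, "ci_lo": lo, "ci_hi": hi})
        rows.append(row)
    return pd.DataFrame(rows)


def stratify(
    assessments: pd.DataFrame,
    cohort: pd.DataFrame,
    by: str,
) -> pd.DataFrame:
    """Polypharmacy proportion by stratum of the cohort.

    by : 'age_band', 'cgis_band' (exclusive strata) or 'comorbidity'
        (non-exclusive; a patient may appear in several strata).
    Empty strata are omitted.
    """
    from .cohort import AGE_BANDS, CGIS_BANDS, COMORBIDITY_CODES, age_band

    merged = assessments.merge(cohort, on="patient_id")
    merged = merged[merged["qualifying"]]
    rows = []
    if by == "age_band":
        strata = [(b, merged[merged["age_at_index"].map(age_band) == b]) for b in AGE_BANDS]
    elif by == "cgis_band":
        strata = [(b, merged[merged["baseline_cgis_band"] == b]) for b in CGIS_BANDS]
    elif by == "comorbidity":
        strata = [
            (label, merged[merged[f"como_{label}"]])
            for label in COMORBIDITY_CODES
            if f"como_{label}" in merged.columns
        ]
    else:
        raise ValueError(f"unknown stratifier: {by!r}")
    for label, grp in strata:
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["polypharmacy"].sum())
        rows.append((label, n, k, percentage(k, n)))
    return pd.DataFrame(rows, columns=["stratum", "n", "n_polypharmacy", "pct_polypharmacy"])


def combination_counts(
    episodes: pd.DataFrame,
    cohort: pd.DataFrame,
    window_offsets: tuple[int, int] = (-14, 14),
    min_overlap_days: int = DEFAULT_MIN_OVERLAP_DAYS,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Patients per unordered drug pair with ≥min_overlap_days of mutual
    in-window overlap (a patient can count toward several pairs).

    Returns (drug_a, drug_b, n, pct) sorted by descending n then
    lexicographically; pct is of the cohort size.
    """
    ep_by_pt = dict(tuple(episodes.groupby("patient_id"))) if not episodes.empty else {}
    n_total = len(cohort)
    counts: dict[tuple[str, str], int] = {}
    for pid, index_day in zip(cohort["patient_id"], cohort["index_date"]):
        eps = ep_by_pt.get(pid)
        if eps is None:
            continue
        win = (int(index_day) + window_offsets[0], int(index_day) + window_offsets[1])
        in_win = eps[(eps["start"] <= win[1]) & (eps["end"] >= win[0])]
        by_drug = dict(tuple(in_win.groupby("drug_name")))
        for a, b in combinations(sorted(by_drug), 2):
            if _pair_overlap_days(by_drug[a], by_drug[b], win) >= min_overlap_days:
                counts[(a, b)] = counts.get((a, b), 0) + 1
    rows = [
        (a, b, n, percentage(n, n_total) if n_total else float("nan"))
        for (a, b), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["drug_a", "drug_b", "n", "pct"])
    df = df.sort_values(["n", "drug_a", "drug_b"], ascending=[False, True, True]).reset_index(drop=True)
    if top_k is not None:
        if top_k <= 0:
            raise ValueError("top_k must be positive")
        df = df.head(top_k)
    return df
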