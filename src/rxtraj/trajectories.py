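"""Treatment journeys: class-level state sequences, change events,
Sankey edge lists and treatment-continuation percentages.

A patient's *journey* over an analysis window is the ordered sequence of
maximal intervals on which the set of active medication classes is
constant (the empty set — no treatment — is a state too, labelled
"none").  A *treatment change* is the initiation of any new medication
episode, at drug level, regardless of whether earlier treatment
continues: an add-on and a within-class switch both count, while a
re-prescription already merged into an existing episode does not.

Treatment continuation for a medication class is the percentage of the
window's days covered by at least one episode of that class, summarised
across patients as mean (SD) with a normal-theory 95% CI.

Functions here operate on *index-relative* episodes: call
``rebase_to_index`` first so that day 0 is each patient's index date and
windows such as (0, 364) — the 12 months post baseline — are shared by
all patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import MeanCI, normal_mean_ci, round_half_up

CONTINUED = "continued"

#: 12-month windows in closed-interval day counting
POST_WINDOW = (0, 364)
PRE_WINDOW = (-365, -1)


def rebase_to_index(episodes: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Shift episode days so each patient's index date is day 0.

    Episodes of patients absent from the cohort are dropped.
    """
    idx = cohort.set_index("patient_id")["index_date"]
    df = episodes[episodes["patient_id"].isin(idx.index)].copy()
    shift = df["patient_id"].map(idx)
    df["start"] = df["start"] - shift
    df["end"] = df["end"] - shift
    return df


def state_label(classes) -> str:
    """Deterministic label: sorted class names joined by '+', or 'none'."""
    return "+".join(sorted(classes)) if classes else "none"


def _clip(eps: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    w0, w1 = window
    df = eps[(eps["start"] <= w1) & (eps["end"] >= w0)].copy()
    df["start"] = df["start"].clip(lower=w0)
    df["end"] = df["end"].clip(upper=w1)
    return df


def _patient_states(eps: pd.DataFrame, window: tuple[int, int]) -> list[tuple[frozenset, int, int]]:
    """Maximal constant active-class-set intervals tiling the window."""
    w0, w1 = window
    eps = _clip(eps, window)
    cuts = {w0, w1 + 1}
    cuts.update(int(s) for s in eps["start"])
    cuts.update(int(e) + 1 for e in eps["end"])
    cuts = sorted(c for c in cuts if w0 <= c <= w1 + 1)
    out: list[tuple[frozenset, int, int]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        active = frozenset(
            eps.loc[(eps["start"] <= a) & (eps["end"] >= b - 1), "med_class"]
        )
        if out and out[-1][0] == active:  # merge equal neighbours
            out[-1] = (active, out[-1][1], b - 1)
        else:
            out.append((active, a, b - 1))
    return out


def state_sequence(
    episodes: pd.DataFrame,
    window: tuple[int, int],
    patients=None,
) -> pd.DataFrame:
    """Journey states for each patient.

    Parameters
    ----------
    episodes : index-relative, class-annotated, gap-merged episodes.
    window : closed (start, end) in index-relative days.
    patients : iterable restricting/extending the patient set; patients
        with no in-window episodes get a single 'none' state.  Defaults
        to the patients present in `episodes`.

    Returns
    -------
    DataFrame (patient_id, classes, label, start, end, ordinal) whose
    intervals exactly tile the window for every patient.
    """
    if window[1] < window[0]:
        raise ValueError("window end before start")
    if patients is None:
        patients = episodes["patient_id"].unique()
    ep_by_pt = dict(tuple(episodes.groupby("patient_id"))) if not episodes.empty else {}
    empty = episodes.iloc[0:0]
    rows = []
    for pid in patients:
        for i, (classes, s, e) in enumerate(_patient_states(ep_by_pt.get(pid, empty), window)):
            rows.append((pid, classes, state_label(classes), s, e, i))
    return pd.DataFrame(rows, columns=["patient_id", "classes", "label", "start", "end", "ordinal"])


def detect_changes(episodes: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Drug-level treatment-change events.

    One event per merged episode starting strictly after the window
    start and no later than the window end.

    Returns DataFrame (patient_id, day, drug_name) sorted by
    (patient_id, day, drug_name).
    """
    w0, w1 = window
    if episodes.empty:
        return pd.DataFrame(columns=["patient_id", "day", "drug_name"])
    ev = episodes[(episodes["start"] > w0) & (episodes["start"] <= w1)]
    out = ev[["patient_id", "start", "drug_name"]].rename(columns={"start": "day"})
    return out.sort_values(["patient_id", "day", "drug_name"]).reset_index(drop=True)


def journey_to_first_change(
    episodes: pd.DataFrame,
    window: tuple[int, int],
    patients=None,
    require_baseline: bool = True,
) -> pd.DataFrame:
    """Initial state and state after the first treatment change.

    For the post-baseline window the initial state is the class set
    active on the window start day; an empty initial state raises,
    because cohort inclusion guarantees baseline treatment.  With
    ``require_baseline=False`` (the pre-baseline analysis) the initial
    state is the first non-empty state in the window and untreated
    patients are omitted.

    The journey outcome is the class set active on the day of the first
    drug-level change event after the anchor day, or 'continued' if no
    change occurs in the window.

    Returns DataFrame (patient_id, initial, outcome, label) where
    initial/outcome are state labels and label is "initial -> outcome".
    """
    if patients is None:
        patients = episodes["patient_id"].unique()
    ep_by_pt = dict(tuple(episodes.groupby("patient_id"))) if not episodes.empty else {}
    empty = episodes.iloc[0:0]
    w0, w1 = window
    rows = []
    for pid in patients:
        eps = ep_by_pt.get(pid, empty)
        active0 = frozenset(eps.loc[(eps["start"] <= w0) & (eps["end"] >= w0), "med_class"])
        if active0:
            anchor = w0
        elif require_baseline:
            raise ValueError(
                f"patient {pid!r} has no active treatment at window start; "
                "should have failed cohort inclusion"
            )
        else:
            in_win = _clip(eps, window)
            if in_win.empty:
                continue  # never treated in window: not part of this sub-cohort
            anchor = int(in_win["start"].min())
            active0 = frozenset(in_win.loc[in_win["start"] == anchor, "med_class"])
        changes = eps.loc[(eps["start"] > anchor) & (eps["start"] <= w1), "start"]
        if changes.empty:
            outcome = CONTINUED
        else:
            day = int(changes.min())
            outcome = state_label(
                frozenset(eps.loc[(eps["start"] <= day) & (eps["end"] >= day), "med_class"])
            )
        init = state_label(active0)
        rows.append((pid, init, outcome, f"{init} -> {outcome}"))
    return pd.DataFrame(rows, columns=["patient_id", "initial", "outcome", "label"])


def top_k_journeys(journeys: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k most common journey labels with n and % of the sub-cohort.

    Ties broken lexicographically by label; percentages half-up to one
    decimal.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n_total = len(journeys)
    counts = (
        journeys.groupby("label").size().reset_index(name="n")
        .sort_values(["n", "label"], ascending=[False, True])
        .reset_index(drop=True)
    )
    counts["pct"] = counts["n"].map(lambda n: round_half_up(100.0 * n / n_total))
    return counts.head(k)


def sankey_edges(states: pd.DataFrame, max_steps: int | None = None) -> pd.DataFrame:
    """Aggregate per-step transitions between journey states.

    An edge (source, target, step, n) counts patients whose state of
    ordinal step−1 has label `source` and state of ordinal step has
    label `target`.  The full edge list is always returned; use
    ``prune_edges`` for a display copy.
    """
    if states.empty:
        return pd.DataFrame(columns=["source", "target", "step", "n"])
    df = states.sort_values(["patient_id", "ordinal"])
    nxt = df.groupby("patient_id").shift(-1)
    mask = nxt["label"].notna()
    trans = pd.DataFrame(
        {
            "source": df.loc[mask, "label"],
            "target": nxt.loc[mask, "label"],
            "step": (df.loc[mask, "ordinal"] + 1).astype(int),
        }
    )
    if max_steps is not None:
        trans = trans[trans["step"] <= max_steps]
    edges = (
        trans.groupby(["source", "target", "step"]).size().reset_index(name="n")
        .sort_values(["step", "n", "source", "target"], ascending=[True, False, True, True])
        .reset_index(drop=True)
    )
    return edges


def prune_edges(edges: pd.DataFrame, min_count: int) -> pd.DataFrame:
    """Display filter: drop edges with n < min_count (full list untouched)."""
    return edges[edges["n"] >= min_count].reset_index(drop=True)


@dataclass(frozen=True)
class ContinuationResult:
    med_class: str
    n_patients: int
    mean_pct: float
    sd_pct: float
    ci: MeanCI | None
    stratum: str | None = None


def _coverage_days(eps: pd.DataFrame, window: tuple[int, int]) -> int:
    """Days of `window` covered by ≥1 of the given episodes."""
    clipped = _clip(eps, window)
    if clipped.empty:
        return 0
    ivs = clipped[["start", "end"]].sort_values(["start", "end"]).to_numpy()
    total, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    return int(total + cur_e - cur_s + 1)


def continuation_percentage(
    episodes: pd.DataFrame,
    med_class: str,
    window: tuple[int, int] = POST_WINDOW,
    patients=None,
) -> tuple[pd.Series, ContinuationResult]:
    """Per-patient and aggregate continuation for one medication class.

    Per patient: 100 × (window days covered by ≥1 episode of the class)
    / window length.  Patients default to those with ≥1 in-window episode
    of the class; pass `patients` to fix the denominator population
    (e.g. only patients with ≥12 months of data).

    Returns (per-patient Series indexed by patient_id, ContinuationResult
    with mean, SD and normal-theory 95% CI, all unrounded).
    """
    w0, w1 = window
    if w1 < w0:
        raise ValueError("zero- or negative-length window")
    length = w1 - w0 + 1
    cls = episodes[episodes["med_class"] == med_class]
    cls = cls[(cls["start"] <= w1) & (cls["end"] >= w0)]
    if patients is None:
        patients = sorted(cls["patient_id"].unique())
    ep_by_pt = dict(tuple(cls.groupby("patient_id")))
    empty = cls.iloc[0:0]
    vals = {
        pid: 100.0 * _coverage_days(ep_by_pt.get(pid, empty), window) / length
        for pid in patients
    }
    per_patient = pd.Series(vals, name=f"continuation_{med_class}")
    n = len(per_patient)
    if n == 0:
        return per_patient, ContinuationResult(med_class, 0, float("nan"), float("nan"), None)
    mean = float(per_patient.mean())
    sd = float(per_patient.std(ddof=1)) if n > 1 else 0.0
    return per_patient, ContinuationResult(med_class, n, mean, sd, normal_mean_ci(mean, sd, n))


def continuation_by_symptom(
    episodes: pd.DataFrame,
    symptom_labels: pd.DataFrame,
    classes,
    window: tuple[int, int] = POST_WINDOW,
    patients=None,
) -> pd.DataFrame:
    """Mean (SD) continuation per class, per (non-exclusive) symptom stratum.

    Strata with no contributing patients for a class yield NaN cells.
    Returns long DataFrame (symptom, med_class, n, mean_pct, sd_pct).
    """
    rows = []
    strata = sorted(symptom_labels["category"].unique()) if not symptom_labels.empty else []
    for symptom in strata:
        members = set(symptom_labels.loc[symptom_labels["category"] == symptom, "patient_id"])
        if patients is not None:
            members &= set(patients)
        sub = episodes[episodes["patient_id"].isin(members)]
        for med_class in classes:
            per_pt, res = continuation_percentage(sub, med_class, window)
            if res.n_patients == 0:
                rows.append((symptom, med_class, 0, float("nan"), float("nan")))
            else:
                rows.append((symptom, med_class, res.n_patients, res.mean_pct, res.sd_pct))
    return pd.DataFrame(rows, columns=["symptom", "med_class", "n", "mean_pct", "sd_pct"])
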