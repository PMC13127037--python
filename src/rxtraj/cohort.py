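"""Cohort derivation: index date, inclusion/exclusion cascade, attrition.

The analysis cohort anchors every patient at an *index date* — the first
recorded borderline-personality-disorder diagnosis (ICD-9 301.83 /
ICD-10 F60.3) — and then applies, in order:

1. age at index ≥ 12 completed years;
2. ≥1 psychotropic prescription episode intersecting the ±14-day baseline
   window around index, with total episode length ≥ 14 days;
3. visit records extending ≥ 52 weeks past the index date;
4. no lifetime diagnosis of schizophrenia, schizoaffective disorder,
   schizophreniform disorder, bipolar I disorder or delusional disorder;
5. no *current* diagnosis (recorded within a configurable window around
   index) of paranoid, schizoid, schizotypal or antisocial personality
   disorder.

A patient's exclusion_reason is the first criterion failed in this order;
the eligible set itself is order-independent.  Ages are completed years at
index; all dates are integer day offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .episodes import ClassMap, merge_gaps
from .stats import percentage

INDEX_CODES = frozenset({"301.83", "F60.3"})

# representative ICD-9/ICD-10 pairs for each exclusion diagnosis
LIFETIME_EXCLUSION_CODES = frozenset(
    {
        "295.90", "F20.9",    # schizophrenia
        "295.70", "F25.0",    # schizoaffective disorder
        "295.40", "F20.81",   # schizophreniform disorder
        "296.44", "F31.13",   # bipolar I disorder
        "297.1", "F22",       # delusional disorder
    }
)
CURRENT_EXCLUSION_CODES = frozenset(
    {
        "301.0", "F60.0",     # paranoid PD
        "301.20", "F60.1",    # schizoid PD
        "301.22", "F21",      # schizotypal PD
        "301.7", "F60.2",     # antisocial PD
    }
)

# psychiatric comorbidities reported in the baseline table
COMORBIDITY_CODES: dict[str, frozenset[str]] = {
    "MDD": frozenset({"296.32", "F33.1"}),
    "anxiety": frozenset({"300.02", "F41.1"}),
    "SUD": frozenset({"304.80", "F10.20"}),
    "PTSD": frozenset({"309.81", "F43.10"}),
    "other_bipolar": frozenset({"296.89", "F31.81"}),
    "other_psychiatric": frozenset({"300.9", "F99"}),
    "other_mood": frozenset({"300.4", "F34.1"}),
    "ADHD": frozenset({"314.01", "F90.0"}),
    "OCD": frozenset({"300.3", "F42.2"}),
    "eating": frozenset({"307.50", "F50.9"}),
    "bipolar_I": frozenset({"296.44", "F31.13"}),
}

AGE_BANDS = ("12-17", "18-25", "26-35", "36-45", "46-55", "56-65", ">65")
CGIS_BANDS = ("1-3", "4-5", "6-7", "missing")

CRITERIA = (
    "index_diagnosis",
    "age",
    "baseline_treatment",
    "followup",
    "lifetime_exclusion",
    "current_exclusion",
)


@dataclass(frozen=True)
class CohortSpec:
    """Thresholds and code sets for cohort selection."""

    baseline_halfwidth: int = 14          # days either side of index
    min_treatment_days: int = 14          # minimum baseline episode length
    min_followup_weeks: int = 52
    min_age_years: int = 12
    index_codes: frozenset[str] = INDEX_CODES
    current_exclusion_codes: frozenset[str] = CURRENT_EXCLUSION_CODES
    lifetime_exclusion_codes: frozenset[str] = LIFETIME_EXCLUSION_CODES
    current_window_days: int = 365        # look-back defining a "current" diagnosis
    gap_days: int = 60                    # episode merge threshold for the baseline test

    def __post_init__(self):
        for name in (
            "baseline_halfwidth", "min_treatment_days", "min_followup_weeks",
            "min_age_years", "current_window_days", "gap_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"CohortSpec.{name} must be strictly positive")
        if self.index_codes & (self.current_exclusion_codes | self.lifetime_exclusion_codes):
            raise ValueError("index codes overlap exclusion codes")


def age_at(day: int, birth_day: int) -> int:
    """Completed years of age on `day` for a patient born on `birth_day`."""
    return int(math.floor((day - birth_day) / 365.25))


def cgis_band(score) -> str:
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "missing"
    score = int(score)
    if 1 <= score <= 3:
        return "1-3"
    if 4 <= score <= 5:
        return "4-5"
    if 6 <= score <= 7:
        return "6-7"
    raise ValueError(f"CGI-S score out of range: {score}")


def age_band(age: int) -> str:
    if age < 12:
        raise ValueError("age below cohort minimum")
    for lo, hi, label in (
        (12, 17, "12-17"), (18, 25, "18-25"), (26, 35, "26-35"),
        (36, 45, "36-45"), (46, 55, "46-55"), (56, 65, "56-65"),
    ):
        if lo <= age <= hi:
            return label
    return ">65"


def find_index_date(diagnoses: pd.DataFrame, spec: CohortSpec | None = None) -> dict:
    """Earliest index-code diagnosis day per patient.

    Patients with no index diagnosis are absent from the returned map.
    """
    spec = spec or CohortSpec()
    if diagnoses.empty:
        return {}
    codes = diagnoses["code"].astype(str).str.strip()
    hit = diagnoses[codes.isin(spec.index_codes)]
    return hit.groupby("patient_id")["day"].min().to_dict()


def _comorbidity_flags(pt_codes_days: list[tuple[str, int]], index_day: int, spec: CohortSpec) -> dict:
    lo = index_day - spec.current_window_days
    hi = index_day + spec.baseline_halfwidth
    flags = {}
    for label, codes in COMORBIDITY_CODES.items():
        flags[label] = any(c in codes and lo <= d <= hi for c, d in pt_codes_days)
    return flags


def apply_criteria(
    raw,
    spec: CohortSpec | None = None,
    class_map: ClassMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion/exclusion cascade.

    Parameters
    ----------
    raw : RawTables (or any object with .demographics, .diagnoses,
        .prescriptions, .visits, .assessments DataFrames).
    spec : thresholds and code sets.
    class_map : defines the psychotropic universe for the baseline
        treatment criterion; packaged map by default.

    Returns
    -------
    (cohort, attrition): cohort has one row per patient with an index
    diagnosis (columns patient_id, index_date, age_at_index, gender, race,
    ethnicity, baseline_cgis_band, como_<label>…, eligible,
    exclusion_reason); attrition lists survivors after each criterion.
    """
    spec = spec or CohortSpec()
    class_map = class_map or ClassMap.packaged()

    idx_map = find_index_date(raw.diagnoses, spec)
    empty_cohort = pd.DataFrame(
        columns=["patient_id", "index_date", "age_at_index", "gender", "race",
                 "ethnicity", "baseline_cgis_band", "eligible", "exclusion_reason"]
    )
    if not idx_map:
        attrition = pd.DataFrame({"criterion": CRITERIA, "n_remaining": [0] * len(CRITERIA)})
        return empty_cohort, attrition

    demo = raw.demographics.set_index("patient_id")
    dx_by_pt = {
        pid: list(zip(g["code"].astype(str).str.strip(), g["day"]))
        for pid, g in raw.diagnoses.groupby("patient_id")
    }
    last_visit = raw.visits.groupby("patient_id")["day"].max().to_dict() if not raw.visits.empty else {}

    # merged psychotropic episodes for the baseline-treatment criterion
    rx = raw.prescriptions
    if not rx.empty:
        rx = rx[rx["drug_name"].map(lambda d: d in class_map)]
    episodes = merge_gaps(rx, spec.gap_days) if not rx.empty else pd.DataFrame(
        columns=["patient_id", "drug_name", "start", "end", "n_source_records"]
    )
    ep_by_pt = dict(tuple(episodes.groupby("patient_id"))) if not episodes.empty else {}

    assess_by_pt = dict(tuple(raw.assessments.groupby("patient_id"))) if not raw.assessments.empty else {}

    rows = []
    for pid in sorted(idx_map):
        index_day = int(idx_map[pid])
        d = demo.loc[pid]
        age = age_at(index_day, int(d["birth_day"]))
        pt_dx = dx_by_pt.get(pid, [])

        failures = []
        if age < spec.min_age_years:
            failures.append("age")

        win_lo, win_hi = index_day - spec.baseline_halfwidth, index_day + spec.baseline_halfwidth
        eps = ep_by_pt.get(pid)
        ok_baseline = False
        if eps is not None:
            inter = (eps["start"] <= win_hi) & (eps["end"] >= win_lo)
            lengths = eps["end"] - eps["start"] + 1
            ok_baseline = bool((inter & (lengths >= spec.min_treatment_days)).any())
        if not ok_baseline:
            failures.append("baseline_treatment")

        if last_visit.get(pid, -np.inf) < index_day + 7 * spec.min_followup_weeks:
            failures.append("followup")

        if any(c in spec.lifetime_exclusion_codes for c, _ in pt_dx):
            failures.append("lifetime_exclusion")

        cur_lo = index_day - spec.current_window_days
        cur_hi = index_day + spec.baseline_halfwidth
        if any(c in spec.current_exclusion_codes and cur_lo <= day <= cur_hi for c, day in pt_dx):
            failures.append("current_exclusion")

        # CGI-S nearest the index within the baseline window
        band = "missing"
        a = assess_by_pt.get(pid)
        if a is not None:
            a_win = a[(a["day"] >= win_lo) & (a["day"] <= win_hi)]
            if not a_win.empty:
                nearest = a_win.iloc[(a_win["day"] - index_day).abs().argsort(kind="stable")].iloc[0]
                band = cgis_band(nearest["cgis"])

        row = {
            "patient_id": pid,
            "index_date": index_day,
            "age_at_index": age,
            "gender": d["gender"],
            "race": d["race"],
            "ethnicity": d["ethnicity"],
            "baseline_cgis_band": band,
            "eligible": not failures,
            "exclusion_reason": failures[0] if failures else None,
            "_failures": frozenset(failures),
        }
        for label, val in _comorbidity_flags(pt_dx, index_day, spec).items():
            row[f"como_{label}"] = val
        rows.append(row)

    cohort = pd.DataFrame(rows)

    # attrition: survivors after each criterion, in declared order
    n = len(cohort)
    counts = [("index_diagnosis", n)]
    surviving = cohort
    for crit in CRITERIA[1:]:
        surviving = surviving[~surviving["_failures"].map(lambda f: crit in f)]
        counts.append((crit, len(surviving)))
    attrition = pd.DataFrame(counts, columns=["criterion", "n_remaining"])

    cohort = cohort.drop(columns="_failures")
    return cohort, attrition


def eligible_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["eligible"]].reset_index(drop=True)


def baseline_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by age band, gender, race, ethnicity and
    comorbidity for an (eligible) cohort.

    Returns a long table (section, category, n, pct) with percentages of
    the cohort size, rounded half-up to 1 decimal.  Comorbidity rows are
    non-exclusive.
    """
    if cohort.empty:
        raise ValueError("baseline_summary needs a non-empty cohort")
    n_total = len(cohort)
    rows = []

    bands = cohort["age_at_index"].map(age_band)
    for b in AGE_BANDS:
        k = int((bands == b).sum())
        rows.append(("age_band", b, k, percentage(k, n_total)))
    for section, col in (("gender", "gender"), ("race", "race"), ("ethnicity", "ethnicity")):
        for cat, k in cohort[col].value_counts().sort_index().items():
            rows.append((section, cat, int(k), percentage(int(k), n_total)))
    for label in COMORBIDITY_CODES:
        col = f"como_{label}"
        if col in cohort.columns:
            k = int(cohort[col].sum())
            rows.append(("comorbidity", label, k, percentage(k, n_total)))
    return pd.DataFrame(rows, columns=["section", "category", "n", "pct"])
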