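"""Seeded synthetic EHR generator.

Emulates the longitudinal structure the trajectory analysis assumes —
irregular visit cadence, overlapping prescriptions, short PRN courses,
same-drug re-prescription gaps, comorbidity-conditional prescribing and
realistic demographic margins — so every downstream stage can be tested
without access to any proprietary source database.

The prescribing process is deliberately simple and analysable:

* each medication class is initiated at baseline independently with its
  configured probability (optionally boosted by comorbidities), one drug
  per class, starting within the 14 days before the index date and
  lasting at least ``baseline_min_duration`` days;
* pre-baseline courses end well before the baseline window and
  post-baseline initiations (per-class daily switch hazard) start after
  it, so the baseline polypharmacy rate has a closed form
  (``expected_baseline_multidrug_rate``);
* re-prescriptions of the same drug follow a configurable gap
  distribution straddling the 60-day merge threshold, and PRN courses
  are shorter than the 14-day minimum-duration filter.

All dates are integer day offsets from a per-run epoch; the root seed is
split into one child stream per output table, so adding a table cannot
perturb existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .episodes import MED_CLASSES

BOOST_CAP = 0.98

TABLE_COLUMNS = {
    "demographics": ["patient_id", "birth_day", "gender", "race", "ethnicity"],
    "diagnoses": ["patient_id", "code", "code_system", "day"],
    "prescriptions": ["patient_id", "drug_name", "start_day", "end_day"],
    "visits": ["patient_id", "day"],
    "assessments": ["patient_id", "day", "cgis"],
    "symptom_labels": ["patient_id", "day", "category"],
}

# (ICD-9, ICD-10) code pair per generated diagnosis label
DX_CODES: dict[str, tuple[str, str]] = {
    "MDD": ("296.32", "F33.1"),
    "anxiety": ("300.02", "F41.1"),
    "SUD": ("304.80", "F10.20"),
    "PTSD": ("309.81", "F43.10"),
    "other_bipolar": ("296.89", "F31.81"),
    "other_psychiatric": ("300.9", "F99"),
    "other_mood": ("300.4", "F34.1"),
    "ADHD": ("314.01", "F90.0"),
    "OCD": ("300.3", "F42.2"),
    "eating": ("307.50", "F50.9"),
    "bipolar_I": ("296.44", "F31.13"),          # lifetime exclusion
    "schizophrenia": ("295.90", "F20.9"),        # lifetime exclusion
    "antisocial_pd": ("301.7", "F60.2"),         # current exclusion
    "paranoid_pd": ("301.0", "F60.0"),           # current exclusion
}
LIFETIME_EXCLUSION_LABELS = ("bipolar_I", "schizophrenia")
CURRENT_EXCLUSION_LABELS = ("antisocial_pd", "paranoid_pd")

# per-class drug menu with prescribing weights (most-prescribed first)
DRUG_WEIGHTS: dict[str, list[tuple[str, float]]] = {
    "antidepressant": [
        ("sertraline", 0.18), ("fluoxetine", 0.16), ("citalopram", 0.15),
        ("trazodone", 0.13), ("escitalopram", 0.09), ("venlafaxine", 0.08),
        ("bupropion", 0.07), ("duloxetine", 0.06), ("mirtazapine", 0.05),
        ("paroxetine", 0.03),
    ],
    "SGA": [
        ("quetiapine", 0.34), ("aripiprazole", 0.29), ("risperidone", 0.14),
        ("olanzapine", 0.12), ("ziprasidone", 0.06), ("lurasidone", 0.05),
    ],
    "FGA": [
        ("haloperidol", 0.40), ("chlorpromazine", 0.25),
        ("perphenazine", 0.20), ("fluphenazine", 0.15),
    ],
    "anticonvulsant": [
        ("topiramate", 0.40), ("oxcarbazepine", 0.25),
        ("carbamazepine", 0.20), ("levetiracetam", 0.15),
    ],
    "anxiolytic": [
        ("clonazepam", 0.40), ("lorazepam", 0.20), ("alprazolam", 0.15),
        ("hydroxyzine", 0.13), ("diazepam", 0.07), ("buspirone", 0.05),
    ],
    "hypnotic/sedative": [
        ("zolpidem", 0.45), ("eszopiclone", 0.25),
        ("temazepam", 0.20), ("melatonin", 0.10),
    ],
    "stimulant": [
        ("amphetamine/dextroamphetamine", 0.40), ("methylphenidate", 0.35),
        ("lisdexamfetamine", 0.15), ("modafinil", 0.10),
    ],
    "analgesic": [
        ("ibuprofen", 0.40), ("acetaminophen", 0.30),
        ("naproxen", 0.20), ("tramadol", 0.10),
    ],
    "SUD drug": [
        ("naltrexone", 0.40), ("buprenorphine", 0.30),
        ("acamprosate", 0.15), ("disulfiram", 0.10), ("varenicline", 0.05),
    ],
    "mood stabiliser": [
        ("lamotrigine", 0.52), ("gabapentin", 0.32),
        ("valproate", 0.12), ("lithium", 0.04),
    ],
}


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


def _default_class_probs() -> dict[str, float]:
    # chosen so the implied baseline antidepressant rate is 0.80 and the
    # implied conditional multi-drug rate ≈ 0.83 (see docs/methods.md)
    return {
        "antidepressant": 0.80,
        "SGA": 0.42,
        "anxiolytic": 0.36,
        "mood stabiliser": 0.32,
        "anticonvulsant": 0.20,
        "hypnotic/sedative": 0.16,
        "stimulant": 0.09,
        "analgesic": 0.11,
        "SUD drug": 0.05,
        "FGA": 0.03,
    }


def _default_comorbidity_prevalence() -> dict[str, float]:
    return {
        "MDD": 0.571, "anxiety": 0.345, "PTSD": 0.326, "other_bipolar": 0.314,
        "SUD": 0.307, "other_psychiatric": 0.277, "other_mood": 0.209,
        "ADHD": 0.089, "OCD": 0.078, "eating": 0.069,
        "bipolar_I": 0.05, "schizophrenia": 0.02,
        "antisocial_pd": 0.03, "paranoid_pd": 0.02,
    }


def _default_boosts() -> dict[tuple[str, str], float]:
    return {
        ("MDD", "antidepressant"): 1.10,
        ("anxiety", "anxiolytic"): 1.20,
        ("ADHD", "stimulant"): 3.00,
        ("SUD", "SUD drug"): 4.00,
    }


def _default_duration() -> dict[str, dict]:
    # gamma(shape=2, scale=90): mean 180 days, long right tail
    return {c: {"family": "gamma", "shape": 2.0, "scale": 90.0} for c in MED_CLASSES}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults emulate the margins
    of a US outpatient borderline-personality-disorder cohort."""

    n_patients: int = 1000
    seed: int = 0

    gender_probs: dict = field(default_factory=lambda: {"female": 0.873, "male": 0.126, "unknown": 0.001})
    race_probs: dict = field(default_factory=lambda: {"white": 0.600, "black": 0.082, "other": 0.040, "unknown": 0.278})
    ethnicity_probs: dict = field(default_factory=lambda: {"hispanic": 0.140, "not_hispanic": 0.463, "unknown": 0.397})
    age_mean: float = 35.2
    age_sd: float = 12.8
    age_min: float = 12.0
    age_max: float = 90.0

    comorbidity_prevalence: dict = field(default_factory=_default_comorbidity_prevalence)
    class_initiation_prob: dict = field(default_factory=_default_class_probs)
    comorbidity_boost: dict = field(default_factory=_default_boosts)

    episode_duration: dict = field(default_factory=_default_duration)
    baseline_min_duration: int = 90
    switch_hazard: dict = field(default_factory=lambda: {c: 0.001 for c in MED_CLASSES})
    switch_start_lag: int = 15            # first possible post-baseline initiation
    pre_course_factor: float = 0.5        # per-class pre-baseline initiation multiplier

    regap_prob: float = 0.30
    regap_min: int = 10
    regap_max: int = 90
    prn_rate: float = 1.2                 # Poisson mean of short courses per patient
    prn_max_duration: int = 13

    visit_interval_mean: float = 21.0
    followup_horizon: int = 560           # days of record after index
    pre_index_days: int = 365
    dropout_prob: float = 0.15
    dropout_range: tuple = (100, 350)     # last-visit day (post-index) of dropouts
    index_day_range: tuple = (370, 430)

    cgis_probs: tuple = (0.021, 0.036, 0.052, 0.390, 0.371, 0.085, 0.045)
    cgis_missing_prob: float = 0.04
    symptom_label_prob: dict = field(default_factory=lambda: {
        "emotional dysregulation": 0.55,
        "suicidal intent/ideation": 0.40,
        "impulsivity": 0.30,
        "suicidal attempt/self-injury": 0.25,
    })

    def __post_init__(self):
        if self.n_patients < 0:
            raise GeneratorConfigError("n_patients must be >= 0")
        for name in ("gender_probs", "race_probs", "ethnicity_probs"):
            d = getattr(self, name)
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise GeneratorConfigError(f"{name} must sum to 1")
            if any(not 0 <= p <= 1 for p in d.values()):
                raise GeneratorConfigError(f"{name} has a probability outside [0, 1]")
        if abs(sum(self.cgis_probs) - 1.0) > 1e-9 or len(self.cgis_probs) != 7:
            raise GeneratorConfigError("cgis_probs must be 7 probabilities summing to 1")
        for name in ("comorbidity_prevalence", "class_initiation_prob",
                     "switch_hazard", "symptom_label_prob"):
            if any(not 0 <= p <= 1 for p in getattr(self, name).values()):
                raise GeneratorConfigError(f"{name} has a probability outside [0, 1]")
        for name in ("regap_prob", "dropout_prob", "cgis_missing_prob", "pre_course_factor"):
            if not 0 <= getattr(self, name) <= 1:
                raise GeneratorConfigError(f"{name} must be in [0, 1]")
        if self.prn_rate < 0:
            raise GeneratorConfigError("prn_rate must be >= 0")
        unknown = set(self.class_initiation_prob) - set(MED_CLASSES)
        if unknown:
            raise GeneratorConfigError(f"class_initiation_prob has unknown classes: {sorted(unknown)}")
        for c, spec in self.episode_duration.items():
            if spec.get("family") not in ("gamma", "lognormal", "uniform", "fixed"):
                raise GeneratorConfigError(f"episode_duration[{c!r}]: unknown family")
            if any(v <= 0 for k, v in spec.items() if k != "family"):
                raise GeneratorConfigError(f"episode_duration[{c!r}] must have positive parameters")
        for name in ("baseline_min_duration", "switch_start_lag", "regap_min",
                     "regap_max", "prn_max_duration", "followup_horizon",
                     "pre_index_days"):
            if getattr(self, name) <= 0:
                raise GeneratorConfigError(f"{name} must be strictly positive")
        if self.visit_interval_mean <= 0:
            raise GeneratorConfigError("visit_interval_mean must be strictly positive")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class RawTables:
    """The six tabular outputs of the generator (and of any ingestion)."""

    demographics: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    visits: pd.DataFrame
    assessments: pd.DataFrame
    symptom_labels: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def validate(self) -> None:
        known = set(self.demographics["patient_id"])
        for name, df in self.tables().items():
            missing = set(TABLE_COLUMNS[name]) - set(df.columns)
            if missing:
                raise ValueError(f"{name} missing columns {sorted(missing)}")
            if name != "demographics" and not df.empty:
                orphans = set(df["patient_id"]) - known
                if orphans:
                    raise ValueError(f"{name} has unknown patient ids: {sorted(orphans)[:5]}")
        if not self.prescriptions.empty:
            if (self.prescriptions["end_day"] < self.prescriptions["start_day"]).any():
                raise ValueError("prescriptions with end_day < start_day")

    @classmethod
    def empty(cls) -> "RawTables":
        return cls(**{name: pd.DataFrame(columns=cols) for name, cols in TABLE_COLUMNS.items()})


def _draw_duration(rng: np.random.Generator, spec: dict) -> int:
    fam = spec["family"]
    if fam == "gamma":
        x = rng.gamma(spec["shape"], spec["scale"])
    elif fam == "lognormal":
        x = rng.lognormal(spec["mean"], spec["sigma"])
    elif fam == "uniform":
        return int(rng.integers(int(spec["low"]), int(spec["high"]) + 1))
    else:  # fixed
        x = spec["days"]
    return max(1, int(round(x)))


def _weighted_drug(rng: np.random.Generator, med_class: str) -> str:
    drugs, weights = zip(*DRUG_WEIGHTS[med_class])
    w = np.asarray(weights, dtype=float)
    return drugs[rng.choice(len(drugs), p=w / w.sum())]


def _effective_class_probs(config: GeneratorConfig, comorbidities: set[str]) -> dict[str, float]:
    probs = {}
    for c, p in config.class_initiation_prob.items():
        f = 1.0
        for (como, cls), factor in config.comorbidity_boost.items():
            if cls == c and como in comorbidities:
                f *= factor
        probs[c] = min(p * f, BOOST_CAP)
    return probs


def generate(config: GeneratorConfig) -> RawTables:
    """Generate the six synthetic tables; deterministic for a fixed seed."""
    n = config.n_patients
    if n == 0:
        return RawTables.empty()

    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_demo, rng_dx, rng_rx, rng_visit, rng_ass, rng_sym = (
        np.random.default_rng(s) for s in streams
    )
    pids = [f"P{i:06d}" for i in range(n)]

    # ---- demographics (also draws each patient's index day) ----
    index_days = rng_demo.integers(config.index_day_range[0], config.index_day_range[1] + 1, size=n)
    ages = np.empty(n)
    todo = np.arange(n)
    while todo.size:  # truncated-normal age via resampling
        draw = rng_demo.normal(config.age_mean, config.age_sd, size=todo.size)
        ok = (draw >= config.age_min) & (draw <= config.age_max)
        ages[todo[ok]] = draw[ok]
        todo = todo[~ok]
    birth_days = index_days - np.floor(ages * 365.25).astype(int)

    def _cat(rng, probs: dict, size: int):
        cats = list(probs)
        return rng.choice(cats, p=np.asarray([probs[c] for c in cats]), size=size)

    demographics = pd.DataFrame({
        "patient_id": pids,
        "birth_day": birth_days,
        "gender": _cat(rng_demo, config.gender_probs, n),
        "race": _cat(rng_demo, config.race_probs, n),
        "ethnicity": _cat(rng_demo, config.ethnicity_probs, n),
    })

    # ---- diagnoses ----
    dx_rows = []
    comorbidities: list[set[str]] = []
    icd10 = rng_dx.random(n) < 0.8
    for i, pid in enumerate(pids):
        t0 = int(index_days[i])
        code, system = ("F60.3", "icd10") if icd10[i] else ("301.83", "icd9")
        dx_rows.append((pid, code, system, t0))
        mine = set()
        for label, prev in config.comorbidity_prevalence.items():
            if rng_dx.random() >= prev:
                continue
            mine.add(label)
            c9, c10 = DX_CODES[label]
            ccode, csys = (c10, "icd10") if rng_dx.random() < 0.8 else (c9, "icd9")
            if label in LIFETIME_EXCLUSION_LABELS:
                day = int(rng_dx.integers(t0 - 800, t0 + 101))
            elif label in CURRENT_EXCLUSION_LABELS:
                day = int(rng_dx.integers(t0 - 300, t0 + 15))
            else:
                day = int(rng_dx.integers(t0 - 180, t0 + 15))
            dx_rows.append((pid, ccode, csys, day))
        comorbidities.append(mine)
    diagnoses = pd.DataFrame(dx_rows, columns=TABLE_COLUMNS["diagnoses"])

    # ---- prescriptions ----
    rx_rows = []
    all_drugs = [d for c in MED_CLASSES for d, _ in DRUG_WEIGHTS[c]]
    for i, pid in enumerate(pids):
        t0 = int(index_days[i])
        horizon = t0 + config.followup_horizon
        p_eff = _effective_class_probs(config, comorbidities[i])

        def _maybe_regap(drug: str, end: int, dur_spec: dict):
            if rng_rx.random() < config.regap_prob:
                gap = int(rng_rx.integers(config.regap_min, config.regap_max + 1))
                s2 = end + gap
                if s2 <= horizon:
                    e2 = min(s2 + _draw_duration(rng_rx, dur_spec) - 1, horizon)
                    rx_rows.append((pid, drug, s2, e2))

        for c in MED_CLASSES:
            dur_spec = config.episode_duration[c]
            # pre-baseline course, ending well before the baseline window
            if rng_rx.random() < p_eff.get(c, 0.0) * config.pre_course_factor:
                s = int(rng_rx.integers(t0 - config.pre_index_days, t0 - 219))
                e = min(s + _draw_duration(rng_rx, dur_spec) - 1, t0 - 81)
                rx_rows.append((pid, _weighted_drug(rng_rx, c), s, e))
            # baseline course
            if rng_rx.random() < p_eff.get(c, 0.0):
                drug = _weighted_drug(rng_rx, c)
                s = t0 - int(rng_rx.integers(0, 15))
                dur = config.baseline_min_duration + _draw_duration(rng_rx, dur_spec)
                e = min(s + dur - 1, horizon)
                rx_rows.append((pid, drug, s, e))
                _maybe_regap(drug, e, dur_spec)
            # post-baseline initiations (daily hazard)
            hazard = config.switch_hazard.get(c, 0.0)
            n_days = config.followup_horizon - config.switch_start_lag
            if hazard > 0 and n_days > 0:
                for _ in range(rng_rx.binomial(n_days, hazard)):
                    s = t0 + config.switch_start_lag + int(rng_rx.integers(0, n_days))
                    e = min(s + _draw_duration(rng_rx, dur_spec) - 1, horizon)
                    drug = _weighted_drug(rng_rx, c)
                    rx_rows.append((pid, drug, s, e))
                    _maybe_regap(drug, e, dur_spec)
        # PRN / short courses
        for _ in range(rng_rx.poisson(config.prn_rate)):
            drug = all_drugs[rng_rx.integers(0, len(all_drugs))]
            s = int(rng_rx.integers(t0 - 14, horizon - config.prn_max_duration + 1))
            e = s + int(rng_rx.integers(1, config.prn_max_duration + 1)) - 1
            rx_rows.append((pid, drug, s, e))
    prescriptions = pd.DataFrame(rx_rows, columns=TABLE_COLUMNS["prescriptions"])

    # ---- visits ----
    visit_rows = []
    dropout = rng_visit.random(n) < config.dropout_prob
    for i, pid in enumerate(pids):
        t0 = int(index_days[i])
        last = (
            t0 + int(rng_visit.integers(config.dropout_range[0], config.dropout_range[1] + 1))
            if dropout[i]
            else t0 + config.followup_horizon
        )
        day = t0 - config.pre_index_days
        days = {t0}
        while day <= last:
            days.add(day)
            day += max(1, int(round(rng_visit.exponential(config.visit_interval_mean))))
        visit_rows.extend((pid, d) for d in sorted(days) if d <= last)
    visits = pd.DataFrame(visit_rows, columns=TABLE_COLUMNS["visits"])

    # ---- assessments ----
    ass_rows = []
    scores = np.arange(1, 8)
    for i, pid in enumerate(pids):
        t0 = int(index_days[i])
        if rng_ass.random() >= config.cgis_missing_prob:
            score = int(rng_ass.choice(scores, p=np.asarray(config.cgis_probs)))
            ass_rows.append((pid, t0 + int(rng_ass.integers(-7, 8)), score))
        if rng_ass.random() < 0.5:  # later reassessment
            score = int(rng_ass.choice(scores, p=np.asarray(config.cgis_probs)))
            ass_rows.append((pid, t0 + int(rng_ass.integers(60, 200)), score))
    assessments = pd.DataFrame(ass_rows, columns=TABLE_COLUMNS["assessments"])

    # ---- symptom labels ----
    sym_rows = []
    for i, pid in enumerate(pids):
        t0 = int(index_days[i])
        for cat, p in config.symptom_label_prob.items():
            if rng_sym.random() < p:
                sym_rows.append((pid, t0, cat))
    symptom_labels = pd.DataFrame(sym_rows, columns=TABLE_COLUMNS["symptom_labels"])

    out = RawTables(demographics, diagnoses, prescriptions, visits, assessments, symptom_labels)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# closed-form margins implied by a configuration

def _boost_combos(config: GeneratorConfig):
    """(weight, comorbidity-subset) pairs over boost-bearing comorbidities."""
    labels = sorted({como for (como, _cls) in config.comorbidity_boost})
    prevs = [config.comorbidity_prevalence.get(lbl, 0.0) for lbl in labels]
    for r in range(len(labels) + 1):
        for subset in combinations(range(len(labels)), r):
            w = 1.0
            for j, lbl in enumerate(labels):
                w *= prevs[j] if j in subset else (1 - prevs[j])
            yield w, {labels[j] for j in subset}


def expected_baseline_class_rate(config: GeneratorConfig, med_class: str) -> float:
    """Implied fraction of all generated patients with a baseline course
    of `med_class`, marginalised over boost-bearing comorbidities."""
    return sum(
        w * _effective_class_probs(config, combo)[med_class]
        for w, combo in _boost_combos(config)
    )


def expected_baseline_multidrug_rate(config: GeneratorConfig, conditional: bool = True) -> float:
    """Implied probability of ≥2 baseline classes.

    With ``conditional=True`` (default) the probability is conditioned on
    having at least one baseline class — the relevant margin for a cohort
    whose inclusion requires baseline treatment.
    """
    num = den = 0.0
    for w, combo in _boost_combos(config):
        ps = list(_effective_class_probs(config, combo).values())
        p0 = math.prod(1 - p for p in ps)
        p1 = 0.0
        for j, p in enumerate(ps):
            prod = 1.0
            for k, q in enumerate(ps):
                if k != j:
                    prod *= 1 - q
            p1 += p * prod
        num += w * (1 - p0 - p1)
        den += w * (1 - p0)
    return num / den if conditional else num


# ---------------------------------------------------------------------------
# worked micro-fixture with hand-computed answers

def make_worked_fixture() -> RawTables:
    """A hand-authored 10-patient cohort covering every rule boundary.

    All patients share index day 400 (first diagnosis F60.3/301.83).
    Boundaries covered: 59- vs 60-day re-prescription gap (p01/p02),
    13- vs 14-day baseline course (p03/p04), lifetime bipolar-I exclusion
    (p05), under-age patient (p06), <52 weeks of visits (p07), 13- vs
    14-day two-drug overlap (p08/p09), current antisocial-PD exclusion
    (p10).  Eligible patients: p01, p02, p04, p08, p09.
    """
    long_visits = [35, 120, 220, 320, 400, 480, 560, 650, 770]
    short_visits = [35, 120, 220, 320, 400, 480, 560, 650, 757]  # 51 weeks post-index

    demo = [
        # patient_id, birth_day, gender, race, ethnicity  (age at day 400)
        ("p01", -10600, "female", "white", "not_hispanic"),   # 30
        ("p02", -8914, "female", "white", "hispanic"),        # 25
        ("p03", -14393, "female", "black", "not_hispanic"),   # 40
        ("p04", -12566, "male", "white", "unknown"),          # 35
        ("p05", -10010, "female", "unknown", "not_hispanic"), # 28
        ("p06", -3800, "female", "white", "not_hispanic"),    # 11
        ("p07", -16219, "female", "white", "not_hispanic"),   # 45
        ("p08", -11836, "male", "other", "hispanic"),         # 33
        ("p09", -18045, "female", "white", "not_hispanic"),   # 50
        ("p10", -10302, "female", "white", "unknown"),        # 29
    ]
    dx = [(pid, "F60.3", "icd10", 400) for pid, *_ in demo]
    dx += [
        ("p01", "F33.1", "icd10", 390),    # MDD comorbidity
        ("p05", "F31.13", "icd10", -695),  # bipolar I, ~3 years before index
        ("p10", "301.7", "icd9", 350),     # current antisocial PD
    ]
    rx = [
        ("p01", "sertraline", 400, 430), ("p01", "sertraline", 489, 520),  # gap 59: merges
        ("p02", "sertraline", 400, 430), ("p02", "sertraline", 490, 521),  # gap 60: two episodes
        ("p03", "fluoxetine", 395, 407),                                    # 13-day course
        ("p04", "fluoxetine", 395, 408),                                    # 14-day course
        ("p05", "quetiapine", 390, 500),
        ("p06", "sertraline", 390, 480),
        ("p07", "quetiapine", 390, 500),
        ("p08", "sertraline", 386, 500), ("p08", "quetiapine", 402, 450),  # 13-day in-window overlap
        ("p09", "sertraline", 386, 500), ("p09", "quetiapine", 401, 450),  # 14-day in-window overlap
        ("p10", "quetiapine", 390, 500),
    ]
    visits = [(pid, d) for pid, *_ in demo if pid != "p07" for d in long_visits]
    visits += [("p07", d) for d in short_visits]
    assessments = [
        ("p01", 400, 4), ("p02", 400, 5), ("p03", 398, 4), ("p04", 400, 6),
        ("p05", 400, 4), ("p06", 400, 4), ("p07", 400, 4), ("p08", 400, 3),
        ("p09", 400, 7), ("p10", 400, 4),
    ]
    symptoms = [
        ("p01", 400, "emotional dysregulation"),
        ("p02", 400, "suicidal attempt/self-injury"),
        ("p04", 400, "impulsivity"),
        ("p09", 400, "suicidal intent/ideation"),
    ]
    out = RawTables(
        demographics=pd.DataFrame(demo, columns=TABLE_COLUMNS["demographics"]),
        diagnoses=pd.DataFrame(dx, columns=TABLE_COLUMNS["diagnoses"]),
        prescriptions=pd.DataFrame(rx, columns=TABLE_COLUMNS["prescriptions"]),
        visits=pd.DataFrame(visits, columns=TABLE_COLUMNS["visits"]),
        assessments=pd.DataFrame(assessments, columns=TABLE_COLUMNS["assessments"]),
        symptom_labels=pd.DataFrame(symptoms, columns=TABLE_COLUMNS["symptom_labels"]),
    )
    out.validate()
    return out
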