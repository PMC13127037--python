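"""Tabular I/O and end-to-end pipeline orchestration.

Tables are plain comma-separated UTF-8 CSVs with a header row; all dates
are integer day offsets from an arbitrary per-dataset epoch.  Output
tables start with a ``#``-prefixed comment line stating the denominator
definition used, so a number can never silently drift away from its
population.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, apply_criteria, baseline_summary, eligible_cohort
from .episodes import DEFAULT_GAP_DAYS, DEFAULT_MIN_DAYS, ClassMap, build_episodes
from .polypharmacy import (
    DEFAULT_MIN_OVERLAP_DAYS,
    assess_cohort_window,
    checkpoint_table,
    checkpoint_windows,
    combination_counts,
    stratify,
)
from .stats import round_half_up
from .synth import TABLE_COLUMNS, RawTables
from .trajectories import (
    POST_WINDOW,
    PRE_WINDOW,
    continuation_by_symptom,
    continuation_percentage,
    journey_to_first_change,
    rebase_to_index,
    sankey_edges,
    state_sequence,
    top_k_journeys,
)

logger = logging.getLogger(__name__)

REQUIRED_TABLES = ("demographics", "diagnoses", "prescriptions", "visits")
OPTIONAL_TABLES = ("assessments", "symptom_labels")

_INT_COLUMNS = {
    "demographics": ["birth_day"],
    "diagnoses": ["day"],
    "prescriptions": ["start_day", "end_day"],
    "visits": ["day"],
    "assessments": ["day", "cgis"],
    "symptom_labels": ["day"],
}


def write_tables(raw: RawTables, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in raw.tables().items():
        df.to_csv(out / f"{name}.csv", index=False)
    return out


def read_tables(in_dir) -> tuple[RawTables, pd.DataFrame]:
    """Read and schema-validate the six tables from a directory.

    Missing optional tables (assessments, symptom_labels) become empty;
    a missing required table is fatal.  Malformed rows (non-integer
    days, end before start, CGI-S outside 1–7) are dropped and listed in
    the returned validation report (table, row, reason).
    """
    in_dir = Path(in_dir)
    tables: dict[str, pd.DataFrame] = {}
    report_rows: list[tuple[str, int, str]] = []
    for name, cols in TABLE_COLUMNS.items():
        path = in_dir / f"{name}.csv"
        if not path.exists():
            if name in REQUIRED_TABLES:
                raise FileNotFoundError(f"required table missing: {path}")
            tables[name] = pd.DataFrame(columns=cols)
            continue
        df = pd.read_csv(path, comment="#")
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name}.csv missing columns {sorted(missing)}")
        df = df[cols]
        for col in _INT_COLUMNS[name]:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            for i in df.index[bad]:
                report_rows.append((name, int(i), f"non-integer {col}"))
            df = df[~bad]
            df[col] = coerced[~bad].astype(int)
        if name == "prescriptions" and not df.empty:
            bad = df["end_day"] < df["start_day"]
            for i in df.index[bad]:
                report_rows.append((name, int(i), "end_day before start_day"))
            df = df[~bad]
        if name == "assessments" and not df.empty:
            bad = ~df["cgis"].between(1, 7)
            for i in df.index[bad]:
                report_rows.append((name, int(i), "CGI-S outside 1..7"))
            df = df[~bad]
        tables[name] = df.reset_index(drop=True)
    raw = RawTables(**tables)
    raw.validate()
    report = pd.DataFrame(report_rows, columns=["table", "row", "reason"])
    if len(report):
        logger.warning("dropped %d malformed rows on read", len(report))
    return raw, report


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    input_dir: str
    out_dir: str
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    gap_days: int = DEFAULT_GAP_DAYS
    min_days: int = DEFAULT_MIN_DAYS
    min_overlap_days: int = DEFAULT_MIN_OVERLAP_DAYS
    top_k: int = 5
    prune_min: int = 10
    seed: int | None = None  # recorded in the manifest for provenance

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        spec = CohortSpec(**doc.pop("cohort_spec", {}))
        return cls(cohort_spec=spec, **doc)


def _write_csv(df: pd.DataFrame, path: Path, denominator: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# denominator: {denominator}\n")
        df.to_csv(fh, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write every output table plus a manifest.

    Outputs: attrition.csv, baseline_summary.csv,
    checkpoint_polypharmacy.csv, strata_{age_band,cgis_band,comorbidity}.csv,
    journeys_top5_{pre,post}.csv, sankey_edges.csv (post window, full and
    unpruned), combinations.csv, continuation.csv,
    continuation_by_symptom.csv, validation_report.csv, manifest.json.
    Deterministic for fixed inputs and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw, report = read_tables(config.input_dir)
    spec = config.cohort_spec
    class_map = ClassMap.packaged()

    cohort, attrition = apply_criteria(raw, spec, class_map)
    elig = eligible_cohort(cohort)
    n_elig = len(elig)

    _write_csv(report, out / "validation_report.csv", "rows dropped on read")
    _write_csv(attrition, out / "attrition.csv", "patients with an index diagnosis")
    if n_elig:
        _write_csv(baseline_summary(elig), out / "baseline_summary.csv",
                   f"eligible cohort (n={n_elig})")

    episodes = build_episodes(raw.prescriptions, config.gap_days, config.min_days, class_map)
    episodes = episodes[episodes["patient_id"].isin(set(elig["patient_id"]))]

    windows = checkpoint_windows(spec.baseline_halfwidth)
    ck = checkpoint_table(episodes, elig, windows, config.min_overlap_days)
    _write_csv(ck, out / "checkpoint_polypharmacy.csv",
               "qualifying patients (>=1 active episode in window) per checkpoint")

    base_ass = assess_cohort_window(
        episodes, elig, windows["baseline"], config.min_overlap_days
    )
    for by in ("age_band", "cgis_band", "comorbidity"):
        _write_csv(stratify(base_ass, elig, by), out / f"strata_{by}.csv",
                   "qualifying patients in stratum at baseline")

    combos = combination_counts(
        episodes, elig, windows["baseline"], config.min_overlap_days, top_k=None
    )
    _write_csv(combos, out / "combinations.csv", f"eligible cohort (n={n_elig})")

    eps_rel = rebase_to_index(episodes, elig)
    pids = list(elig["patient_id"])
    for tag, window, require in (("post", POST_WINDOW, False), ("pre", PRE_WINDOW, False)):
        journeys = journey_to_first_change(eps_rel, window, patients=pids, require_baseline=require)
        _write_csv(top_k_journeys(journeys, config.top_k), out / f"journeys_top5_{tag}.csv",
                   f"sub-cohort treated in {tag} window (n={len(journeys)})")
    states = state_sequence(eps_rel, POST_WINDOW, patients=pids)
    _write_csv(sankey_edges(states), out / "sankey_edges.csv",
               f"eligible cohort (n={n_elig}), 12-month post window, unpruned")

    cont_rows = []
    for med_class in sorted(eps_rel["med_class"].unique()) if not eps_rel.empty else []:
        _, res = continuation_percentage(eps_rel, med_class, POST_WINDOW)
        if res.n_patients:
            mean, lo, hi = res.ci.display
            cont_rows.append((med_class, res.n_patients, mean, round_half_up(res.sd_pct), lo, hi))
    _write_csv(
        pd.DataFrame(cont_rows, columns=["med_class", "n", "mean_pct", "sd_pct", "ci_lo", "ci_hi"]),
        out / "continuation.csv",
        "patients with >=1 in-window episode of the class, 12-month post window",
    )
    classes = sorted(eps_rel["med_class"].unique()) if not eps_rel.empty else []
    sym = continuation_by_symptom(eps_rel, raw.symptom_labels, classes, POST_WINDOW, patients=pids)
    _write_csv(sym, out / "continuation_by_symptom.csv",
               "patients in symptom stratum with >=1 in-window episode of the class")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "cohort_spec": dataclasses.asdict(spec) | {
                "index_codes": sorted(spec.index_codes),
                "current_exclusion_codes": sorted(spec.current_exclusion_codes),
                "lifetime_exclusion_codes": sorted(spec.lifetime_exclusion_codes),
            },
            "gap_days": config.gap_days,
            "min_days": config.min_days,
            "min_overlap_days": config.min_overlap_days,
            "top_k": config.top_k,
            "prune_min": config.prune_min,
        },
        "inputs": {
            f.name: _sha256(f) for f in sorted(Path(config.input_dir).glob("*.csv"))
        },
        "n_index": int(len(cohort)),
        "n_eligible": n_elig,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
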