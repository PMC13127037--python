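"""Prescription-episode construction.

Raw prescription rows (patient, drug, start day, end day) are coalesced
into *treatment episodes*: for a given patient and drug, a re-prescription
that begins fewer than ``gap_days`` (default 60) days after the end of the
previous prescription is treated as a continuation of the same episode.
Episodes shorter than ``min_days`` (default 14) are then dropped as PRN /
short-course medication, and each surviving episode is annotated with a
single medication class from a packaged drug→class dictionary.

All intervals are closed on both ends at day granularity: a prescription
with start == end lasts 1 day, and the gap between an episode ending on
day e and a record starting on day s is s − e (so s − e == 60 does *not*
merge under the default threshold, matching a strict "< 60 days" rule).
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

MED_CLASSES = (
    "antidepressant",
    "FGA",
    "SGA",
    "anticonvulsant",
    "anxiolytic",
    "hypnotic/sedative",
    "stimulant",
    "analgesic",
    "SUD drug",
    "mood stabiliser",
)

EPISODE_COLUMNS = ["patient_id", "drug_name", "start", "end", "n_source_records"]

DEFAULT_GAP_DAYS = 60
DEFAULT_MIN_DAYS = 14


class ClassMap:
    """Case-insensitive drug name → medication class lookup.

    Backed by a two-column CSV (drug, med_class).  Every drug maps to
    exactly one class; the packaged default covers the psychotropic
    vocabulary used by the synthetic generator.
    """

    def __init__(self, mapping: dict[str, str]):
        if not mapping:
            raise ValueError("class map is empty")
        self._map = {k.strip().lower(): v for k, v in mapping.items()}
        bad = sorted(set(self._map.values()) - set(MED_CLASSES))
        if bad:
            raise ValueError(f"unknown medication classes in map: {bad}")

    @classmethod
    def from_csv(cls, path) -> "ClassMap":
        df = pd.read_csv(path)
        if not {"drug", "med_class"} <= set(df.columns):
            raise ValueError("class map CSV needs columns drug, med_class")
        dup = df["drug"].str.lower().duplicated()
        if dup.any():
            raise ValueError(f"duplicate drugs in class map: {df['drug'][dup].tolist()}")
        return cls(dict(zip(df["drug"], df["med_class"])))

    @classmethod
    def packaged(cls) -> "ClassMap":
        with resources.as_file(resources.files("rxtraj.data") / "class_map.csv") as p:
            return cls.from_csv(p)

    def get(self, drug: str) -> str | None:
        return self._map.get(drug.strip().lower())

    def __contains__(self, drug: str) -> bool:
        return drug.strip().lower() in self._map

    @property
    def drugs(self) -> list[str]:
        return sorted(self._map)

    def drugs_in_class(self, med_class: str) -> list[str]:
        return sorted(d for d, c in self._map.items() if c == med_class)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "drug_name", "start_day", "end_day"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"prescription table missing columns: {sorted(missing)}")
    bad = records["end_day"] < records["start_day"]
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} prescription rows have end_day < start_day "
            f"(first offender index {records.index[bad][0]})"
        )
    return records


def merge_gaps(records: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS) -> pd.DataFrame:
    """Coalesce raw prescriptions into per-(patient, drug) episodes.

    Records that overlap, touch, or are separated by a gap strictly less
    than ``gap_days`` merge transitively into one episode spanning from
    the earliest start to the latest end.

    Parameters
    ----------
    records : DataFrame with columns patient_id, drug_name, start_day, end_day.
    gap_days : merge threshold; a gap of exactly ``gap_days`` does not merge.

    Returns
    -------
    DataFrame with columns patient_id, drug_name, start, end,
    n_source_records, sorted by (patient_id, drug_name, start).
    """
    if gap_days < 1:
        raise ValueError("gap_days must be >= 1")
    records = _validate_records(records)
    if records.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)

    df = records.sort_values(["patient_id", "drug_name", "start_day", "end_day"])
    out: list[tuple] = []
    for (pid, drug), grp in df.groupby(["patient_id", "drug_name"], sort=True):
        starts = grp["start_day"].to_numpy()
        ends = grp["end_day"].to_numpy()
        cur_start, cur_end, n_src = starts[0], ends[0], 1
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_end < gap_days:  # overlap or bridgeable gap
                cur_end = max(cur_end, e)
                n_src += 1
            else:
                out.append((pid, drug, cur_start, cur_end, n_src))
                cur_start, cur_end, n_src = s, e, 1
        out.append((pid, drug, cur_start, cur_end, n_src))
    return pd.DataFrame(out, columns=EPISODE_COLUMNS)


def episode_length(episodes: pd.DataFrame) -> pd.Series:
    """Length in days of each closed-interval episode (end − start + 1)."""
    return episodes["end"] - episodes["start"] + 1


def filter_min_duration(episodes: pd.DataFrame, min_days: int = DEFAULT_MIN_DAYS) -> pd.DataFrame:
    """Drop episodes shorter than ``min_days`` (PRN / short courses)."""
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    if episodes.empty:
        return episodes.copy()
    return episodes[episode_length(episodes) >= min_days].copy()


def annotate_class(
    episodes: pd.DataFrame,
    class_map: ClassMap | None = None,
    unmapped: str = "drop",
) -> pd.DataFrame:
    """Attach a single med_class to each episode.

    unmapped : 'drop' removes episodes of drugs absent from the map
        (count logged); 'other' keeps them with med_class='other'.
    """
    if class_map is None:
        class_map = ClassMap.packaged()
    if unmapped not in ("drop", "other"):
        raise ValueError("unmapped policy must be 'drop' or 'other'")
    df = episodes.copy()
    if df.empty:
        df["med_class"] = pd.Series(dtype=object)
        return df
    df["med_class"] = df["drug_name"].map(class_map.get)
    n_unmapped = int(df["med_class"].isna().sum())
    if n_unmapped:
        drugs = sorted(df.loc[df["med_class"].isna(), "drug_name"].unique())
        logger.warning("%d episodes of unmapped drugs %s: policy=%s", n_unmapped, drugs, unmapped)
        if unmapped == "drop":
            df = df[df["med_class"].notna()].copy()
        else:
            df["med_class"] = df["med_class"].fillna("other")
    return df


def build_episodes(
    prescriptions: pd.DataFrame,
    gap_days: int = DEFAULT_GAP_DAYS,
    min_days: int = DEFAULT_MIN_DAYS,
    class_map: ClassMap | None = None,
    unmapped: str = "drop",
) -> pd.DataFrame:
    """merge_gaps → filter_min_duration → annotate_class in one call."""
    return annotate_class(
        filter_min_duration(merge_gaps(prescriptions, gap_days), min_days),
        class_map,
        unmapped,
    )
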