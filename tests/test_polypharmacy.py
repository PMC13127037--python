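"""Concurrency sweep, window polypharmacy, checkpoints and combinations."""

import numpy as np
import pandas as pd
import pytest

from rxtraj.episodes import build_episodes, merge_gaps
from rxtraj.polypharmacy import (
    assess_cohort_window,
    assess_window,
    checkpoint_table,
    checkpoint_windows,
    combination_counts,
    concurrency_timeline,
    stratify,
)

from .conftest import random_prescriptions
from .oracles import grid_concurrency, grid_max_concurrency, grid_pair_counts, grid_polypharmacy


def eps(*rows):
    df = pd.DataFrame(rows, columns=["patient_id", "drug_name", "start", "end"])
    df["med_class"] = "antidepressant"
    df["n_source_records"] = 1
    return df


def test_disjoint_episodes_max_one():
    tl = concurrency_timeline(eps(("p", "a", 0, 10), ("p", "b", 20, 30)))
    assert tl.max_in(0, 30) == 1
    assert tl.count_on(15) == 0


def test_three_drugs_sharing_a_day():
    tl = concurrency_timeline(eps(("p", "a", 0, 50), ("p", "b", 40, 80), ("p", "c", 50, 60)))
    assert tl.count_on(50) == 3
    assert tl.max_in(0, 100) == 3


def test_timeline_matches_day_grid():
    rng = np.random.default_rng(5)
    for _ in range(30):
        recs = random_prescriptions(rng, n_patients=1, n_drugs=4)
        e = merge_gaps(recs).rename(columns={})
        tl = concurrency_timeline(e)
        for day in range(0, 400, 7):
            assert tl.count_on(day) == grid_concurrency(e, day)


@pytest.mark.parametrize(
    "b_start,expected",
    [(1, True), (2, False)],  # overlap of [b_start, 30] with [0, 14] in window [0, 14]
)
def test_14_day_overlap_boundary(b_start, expected):
    e = eps(("p", "a", 0, 14), ("p", "b", b_start, 30))
    a = assess_window(e, (0, 14), min_overlap_days=14)
    assert a.polypharmacy is expected
    assert a.n_unique_max == 2


def test_clean_switch_is_not_polypharmacy():
    e = eps(("p", "a", 0, 20), ("p", "b", 21, 60))
    a = assess_window(e, (0, 60))
    assert not a.polypharmacy
    assert a.n_unique_max == 1


def test_non_qualifying_patient():
    a = assess_window(eps(("p", "a", 100, 120)), (0, 50))
    assert not a.qualifying and a.n_unique_max == 0


def test_window_end_before_start_raises():
    with pytest.raises(ValueError):
        assess_window(eps(("p", "a", 0, 10)), (10, 0))


def test_overlap_accumulates_across_episode_pairs():
    # two separate co-active stretches of 7 days each total 14
    e = eps(("p", "a", 0, 100), ("p", "b", 0, 6), ("p", "b", 80, 86))
    assert assess_window(e, (0, 100)).polypharmacy


def test_assess_matches_day_grid_oracle():
    rng = np.random.default_rng(9)
    for _ in range(40):
        recs = random_prescriptions(rng, n_patients=1, n_drugs=4)
        e = merge_gaps(recs)
        win = (int(rng.integers(0, 150)), int(rng.integers(150, 380)))
        a = assess_window(e, win)
        assert a.polypharmacy == grid_polypharmacy(e, win)
        assert a.n_unique_max == grid_max_concurrency(e, win)


def test_widening_window_never_decreases_max(worked):
    e = build_episodes(worked.prescriptions)
    p = e[e.patient_id == "p09"]
    prev = 0
    for halfwidth in (5, 14, 30, 60):
        a = assess_window(p, (400 - halfwidth, 400 + halfwidth))
        assert a.n_unique_max >= prev
        prev = a.n_unique_max


def test_lowering_min_overlap_never_unsets_polypharmacy(worked):
    e = build_episodes(worked.prescriptions)
    p = e[e.patient_id == "p09"]
    flags = [assess_window(p, (386, 414), m).polypharmacy for m in (14, 10, 5, 1)]
    assert flags == sorted(flags)  # once True stays True as threshold drops


def cohort_df(*pids, index=400):
    return pd.DataFrame({"patient_id": pids, "index_date": [index] * len(pids)})


def test_checkpoint_table_degenerate_all_single():
    e = eps(("p", "a", 390, 800), ("q", "b", 390, 800))
    tab = checkpoint_table(e, cohort_df("p", "q"), checkpoint_windows())
    base = tab[tab.checkpoint == "baseline"].iloc[0]
    assert base["n_qualifying"] == 2
    assert base["pct_multi"] == 0.0
    assert base["n_1"] == 2


def test_checkpoint_with_no_qualifying_patients():
    e = eps(("p", "a", 390, 420))
    tab = checkpoint_table(e, cohort_df("p"))
    late = tab[tab.checkpoint == "18_months"].iloc[0]
    assert late["n_qualifying"] == 0
    assert np.isnan(late["pct_multi"])


def test_checkpoint_windows_layout():
    wins = checkpoint_windows()
    assert wins["baseline"] == (-14, 14)
    assert wins["10_weeks"] == (35, 105)
    assert wins["18_months"] == (513, 583)


def test_stratify_age_bands_partition(small_raw):
    from rxtraj.cohort import apply_criteria, eligible_cohort

    cohort, _ = apply_criteria(small_raw)
    elig = eligible_cohort(cohort)
    e = build_episodes(small_raw.prescriptions)
    ass = assess_cohort_window(e, elig, (-14, 14))
    tab = stratify(ass, elig, "age_band")
    assert tab["n"].sum() == int(ass["qualifying"].sum())
    with pytest.raises(ValueError):
        stratify(ass, elig, "shoe_size")


def test_combination_counts_brute_force():
    rng = np.random.default_rng(3)
    recs = random_prescriptions(rng, n_patients=4, n_drugs=4, n_records=6)
    e = merge_gaps(recs)
    cohort = cohort_df(*sorted(recs["patient_id"].unique()), index=100)
    got = combination_counts(e, cohort, (-50, 50))
    by_pt = dict(tuple(e.groupby("patient_id")))
    wins = {pid: (50, 150) for pid in by_pt}
    expected = grid_pair_counts(by_pt, wins)
    assert dict(zip(zip(got["drug_a"], got["drug_b"]), got["n"])) == expected


def test_triple_overlap_counts_all_three_pairs():
    e = eps(("p", "a", 0, 100), ("p", "b", 0, 100), ("p", "c", 0, 100))
    got = combination_counts(e, cohort_df("p", index=50), (-50, 50))
    assert set(zip(got["drug_a"], got["drug_b"])) == {("a", "b"), ("a", "c"), ("b", "c")}
    assert (got["n"] == 1).all()
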