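"""Journey states, change events, Sankey edges and continuation."""

import numpy as np
import pandas as pd
import pytest

from rxtraj.episodes import build_episodes, merge_gaps, annotate_class
from rxtraj.synth import GeneratorConfig, generate
from rxtraj.trajectories import (
    POST_WINDOW,
    continuation_by_symptom,
    continuation_percentage,
    detect_changes,
    journey_to_first_change,
    prune_edges,
    rebase_to_index,
    sankey_edges,
    state_label,
    state_sequence,
    top_k_journeys,
)

from .conftest import random_prescriptions
from .oracles import grid_class_coverage, grid_states


def eps(*rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug_name", "med_class", "start", "end"])


def test_single_episode_single_state():
    s = state_sequence(eps(("p", "a", "antidepressant", 0, 100)), (0, 100))
    assert len(s) == 1
    assert s.iloc[0]["label"] == "antidepressant"
    assert (s.iloc[0]["start"], s.iloc[0]["end"]) == (0, 100)


def test_addon_creates_two_states():
    s = state_sequence(
        eps(("p", "a", "antidepressant", 0, 100), ("p", "q", "SGA", 50, 100)), (0, 100)
    )
    assert list(s["label"]) == ["antidepressant", "SGA+antidepressant"]
    assert list(s["ordinal"]) == [0, 1]


def test_untreated_patient_gets_none_state():
    s = state_sequence(eps(("p", "a", "antidepressant", 0, 10)), (0, 50), patients=["p", "q"])
    q = s[s.patient_id == "q"]
    assert list(q["label"]) == ["none"]
    assert (q.iloc[0]["start"], q.iloc[0]["end"]) == (0, 50)


def test_states_tile_window_and_match_day_grid():
    rng = np.random.default_rng(13)
    for _ in range(30):
        recs = random_prescriptions(rng, n_patients=1, n_drugs=4)
        e = annotate_class(merge_gaps(recs))
        win = (int(rng.integers(0, 100)), int(rng.integers(150, 350)))
        s = state_sequence(e, win)
        # tiling: contiguous, no gaps or overlaps
        assert s.iloc[0]["start"] == win[0] and s.iloc[-1]["end"] == win[1]
        assert (s["start"].iloc[1:].to_numpy() == s["end"].iloc[:-1].to_numpy() + 1).all()
        expected = grid_states(e, win)
        got = list(zip(s["classes"], s["start"], s["end"]))
        assert got == expected


def test_merged_represcription_is_not_a_change():
    recs = pd.DataFrame(
        [("p", "sertraline", 0, 30), ("p", "sertraline", 80, 120)],
        columns=["patient_id", "drug_name", "start_day", "end_day"],
    )
    e = annotate_class(merge_gaps(recs))  # gap 50 merges
    assert detect_changes(e, (0, 365)).empty


def test_addon_is_a_change_even_if_first_drug_continues():
    e = eps(("p", "a", "antidepressant", 0, 300), ("p", "q", "SGA", 100, 200))
    ch = detect_changes(e, (0, 365))
    assert list(zip(ch["day"], ch["drug_name"])) == [(100, "q")]


def test_no_episodes_no_changes():
    assert detect_changes(eps(), (0, 365)).empty


def test_journey_continued():
    j = journey_to_first_change(eps(("p", "a", "antidepressant", 0, 364)), POST_WINDOW)
    assert j.iloc[0]["label"] == "antidepressant -> continued"


def test_within_class_switch_is_a_change_with_same_class_set():
    e = eps(("p", "a", "antidepressant", 0, 99), ("p", "b", "antidepressant", 100, 364))
    j = journey_to_first_change(e, POST_WINDOW)
    assert j.iloc[0]["initial"] == "antidepressant"
    assert j.iloc[0]["outcome"] == "antidepressant"


def test_empty_baseline_state_raises():
    with pytest.raises(ValueError, match="cohort inclusion"):
        journey_to_first_change(eps(("p", "a", "antidepressant", 50, 100)), POST_WINDOW)


def test_pre_window_anchors_at_first_treatment():
    e = eps(("p", "a", "antidepressant", -200, -100), ("p", "q", "SGA", -50, -10))
    j = journey_to_first_change(e, (-365, -1), require_baseline=False)
    assert j.iloc[0]["initial"] == "antidepressant"
    assert j.iloc[0]["outcome"] == "SGA"
    # patient never treated in the window is dropped, not an error
    j2 = journey_to_first_change(
        eps(("q", "a", "antidepressant", 10, 20)), (-365, -1),
        patients=["q"], require_baseline=False,
    )
    assert j2.empty


def test_top_k_journeys_ordering_and_ties():
    j = pd.DataFrame({"label": ["B -> continued"] * 3 + ["A -> continued"] * 3 + ["C -> A"] * 4})
    top = top_k_journeys(j, k=2)
    assert list(top["label"]) == ["C -> A", "A -> continued"]  # tie broken lexicographically
    assert list(top["n"]) == [4, 3]
    assert top["pct"].iloc[0] == 40.0


def test_top_k_clipping_and_validation():
    j = pd.DataFrame({"label": ["A -> continued"]})
    assert len(top_k_journeys(j, k=10)) == 1
    assert top_k_journeys(j, k=10)["pct"].iloc[0] == 100.0
    with pytest.raises(ValueError):
        top_k_journeys(j, k=0)


def test_sankey_edge_aggregation_and_pruning():
    e = pd.concat(
        [
            eps((p, "a", "antidepressant", 0, 364), (p, "q", "SGA", 100, 364))
            for p in ("p1", "p2")
        ]
    )
    states = state_sequence(e, POST_WINDOW)
    edges = sankey_edges(states)
    assert len(edges) == 1
    row = edges.iloc[0]
    assert (row["source"], row["target"], row["step"], row["n"]) == (
        "antidepressant", "SGA+antidepressant", 1, 2,
    )
    assert prune_edges(edges, 3).empty
    assert len(edges) == 1  # full list untouched


def test_sankey_conservation(small_raw):
    """At each step, total edge flow equals patients with that many transitions."""
    from rxtraj.cohort import apply_criteria, eligible_cohort

    cohort, _ = apply_criteria(small_raw)
    elig = eligible_cohort(cohort)
    e = rebase_to_index(build_episodes(small_raw.prescriptions), elig)
    states = state_sequence(e, POST_WINDOW, patients=list(elig["patient_id"]))
    edges = sankey_edges(states)
    n_states = states.groupby("patient_id")["ordinal"].max() + 1
    for step in edges["step"].unique():
        assert edges.loc[edges.step == step, "n"].sum() == int((n_states > step).sum())


def test_full_coverage_is_100_percent():
    per, res = continuation_percentage(eps(("p", "a", "antidepressant", -10, 400)), "antidepressant")
    assert per.iloc[0] == 100.0
    assert res.mean_pct == 100.0 and res.sd_pct == 0.0


def test_continuation_gap_not_counted():
    e = eps(("p", "a", "antidepressant", 0, 99), ("p", "b", "antidepressant", 200, 364))
    per, _ = continuation_percentage(e, "antidepressant")
    assert per.iloc[0] == pytest.approx(100.0 * (100 + 165) / 365)


def test_continuation_matches_day_grid():
    rng = np.random.default_rng(21)
    for _ in range(30):
        recs = random_prescriptions(rng, n_patients=1, n_drugs=4)
        e = annotate_class(merge_gaps(recs))
        win = (0, 300)
        for med_class in e["med_class"].unique():
            per, _ = continuation_percentage(e, med_class, win)
            if len(per):
                expected = 100.0 * grid_class_coverage(e, med_class, win) / 301
                assert per.iloc[0] == pytest.approx(expected)


def test_continuation_bounds_and_monotonicity():
    rng = np.random.default_rng(2)
    recs = random_prescriptions(rng, n_patients=2, n_drugs=3)
    e = annotate_class(merge_gaps(recs))
    per, _ = continuation_percentage(e, "antidepressant", (0, 300))
    assert ((per >= 0) & (per <= 100)).all()
    # adding an episode of the class never decreases coverage
    extra = pd.concat([e, eps(*[(p, "zzz", "antidepressant", 50, 80) for p in per.index])])
    per2, _ = continuation_percentage(extra, "antidepressant", (0, 300))
    assert (per2.loc[per.index] >= per - 1e-12).all()


def test_zero_length_window_raises():
    with pytest.raises(ValueError):
        continuation_percentage(eps(("p", "a", "antidepressant", 0, 10)), "antidepressant", (5, 4))


def test_zero_switch_hazard_means_all_continued():
    """With no post-baseline initiations, no regaps and no PRN, every journey
    continues and every continuation percentage is 100."""
    cfg = GeneratorConfig(
        n_patients=60, seed=5,
        switch_hazard={},
        regap_prob=0.0, prn_rate=0.0, pre_course_factor=0.0,
        episode_duration={c: {"family": "fixed", "days": 600}
                          for c in GeneratorConfig().episode_duration},
    )
    raw = generate(cfg)
    from rxtraj.cohort import apply_criteria, eligible_cohort

    cohort, _ = apply_criteria(raw)
    elig = eligible_cohort(cohort)
    e = rebase_to_index(build_episodes(raw.prescriptions), elig)
    j = journey_to_first_change(e, POST_WINDOW, patients=list(elig["patient_id"]))
    assert (j["outcome"] == "continued").all()
    for med_class in e["med_class"].unique():
        per, res = continuation_percentage(e, med_class)
        assert (per == 100.0).all()


def test_continuation_by_symptom_known_coverage(worked):
    from rxtraj.cohort import apply_criteria, eligible_cohort

    cohort, _ = apply_criteria(worked)
    elig = eligible_cohort(cohort)
    e = rebase_to_index(build_episodes(worked.prescriptions), elig)
    tab = continuation_by_symptom(
        e, worked.symptom_labels, ["antidepressant", "SGA"], POST_WINDOW,
        patients=list(elig["patient_id"]),
    )
    # p09 (suicidal intent/ideation): sertraline rel [-14, 100] covers 101/365 days,
    # quetiapine rel [1, 50] covers 50/365 days
    row = tab[(tab.symptom == "suicidal intent/ideation") & (tab.med_class == "antidepressant")].iloc[0]
    assert row["n"] == 1
    assert row["mean_pct"] == pytest.approx(100.0 * 101 / 365)
    assert row["sd_pct"] == 0.0
    row = tab[(tab.symptom == "suicidal intent/ideation") & (tab.med_class == "SGA")].iloc[0]
    assert row["mean_pct"] == pytest.approx(100.0 * 50 / 365)
    # stratum with no episodes of a class yields an empty (NaN) cell
    row = tab[(tab.symptom == "impulsivity") & (tab.med_class == "SGA")].iloc[0]
    assert row["n"] == 0 and np.isnan(row["mean_pct"])


def test_state_label_deterministic():
    assert state_label({"SGA", "antidepressant"}) == "SGA+antidepressant"
    assert state_label(set()) == "none"
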