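"""Dyad classification, transition accounting, degree and risk sets."""

import numpy as np
import pandas as pd
import pytest

from sepnet.panel import (DyadState, EventCounts, TiePanel, TransitionTable,
                          classify_dyad, count_tie_events, degree_summary,
                          extract_risk_sets, interval_transition_counts,
                          transition_table)

from conftest import all_pairs, make_panel, random_panel


@pytest.mark.parametrize("y_ij,y_ji,expected", [
    (0, 0, DyadState.NULL),
    (1, 0, DyadState.DIRECTIONAL),
    (0, 1, DyadState.DIRECTIONAL),
    (1, 1, DyadState.MUTUAL),
])
def test_classify_dyad(y_ij, y_ji, expected):
    assert classify_dyad(y_ij, y_ji) is expected
    # state is invariant to swapping the two directed indicators
    assert classify_dyad(y_ji, y_ij) is expected


def test_classify_dyad_missing_is_not_null():
    assert classify_dyad(None, 0) is None
    assert classify_dyad(1, None) is None
    with pytest.raises(ValueError):
        classify_dyad(2, 0)


def test_transition_table_single_dyad_null_to_directional():
    panel = make_panel([("a", "b", 2)], n_exams=2)
    tt = transition_table(panel)
    expected = np.zeros((3, 3), dtype=int)
    expected[DyadState.NULL, DyadState.DIRECTIONAL] = 1
    assert (tt.counts == expected).all()
    assert tt.n_reversals == 0


def test_transition_table_direction_reversal():
    # (1,0) then (0,1): a directional tie that changes direction
    panel = make_panel([("a", "b", 1), ("b", "a", 2)], n_exams=2)
    tt = transition_table(panel)
    assert tt.counts[DyadState.DIRECTIONAL, DyadState.DIRECTIONAL] == 1
    assert tt.n_reversals == 1
    ev = count_tie_events(tt)
    # the reversal dissolves one directed tie and forms another
    assert ev.n_dissolved == 1 and ev.n_formed == 1 and ev.n_changed == 1


def _brute_force_table(panel, pairs):
    """Independent per-dyad-per-interval enumeration."""
    counts = np.zeros((3, 3), dtype=int)
    n_rev = 0
    seen = set()
    for (a, b) in pairs:
        if frozenset((a, b)) in seen:
            continue
        seen.add(frozenset((a, b)))
        for t0, t1 in zip(panel.exams[:-1], panel.exams[1:]):
            vals = [panel.y(a, b, t0), panel.y(b, a, t0),
                    panel.y(a, b, t1), panel.y(b, a, t1)]
            if any(v is None for v in vals):
                continue
            s0 = classify_dyad(vals[0], vals[1])
            s1 = classify_dyad(vals[2], vals[3])
            counts[s0, s1] += 1
            if s0 == s1 == DyadState.DIRECTIONAL and vals[2] != vals[0]:
                n_rev += 1
    return counts, n_rev


def test_transition_table_matches_enumeration_on_random_panels(rng):
    for _ in range(5):
        panel = random_panel(rng, n_actors=10, n_exams=4)
        pairs = panel.ever_tied_pairs()
        tt = transition_table(panel)
        counts, n_rev = _brute_force_table(panel, pairs)
        assert (tt.counts == counts).all()
        assert tt.n_reversals == n_rev
        # row sums = number of dyad-intervals starting in each state
        assert (tt.counts.sum(axis=1) == counts.sum(axis=1)).all()


def test_count_tie_events_published_arithmetic():
    tt = TransitionTable(np.array([[2520, 505, 5], [553, 2203, 52], [10, 79, 347]]),
                         n_reversals=6)
    ev = count_tie_events(tt)
    assert ev.n_dissolved == 648
    assert ev.n_formed == 568
    assert ev.n_changed == 1210
    assert ev.n_total == 6274
    assert round(ev.pct_changed, 2) == 19.29


def test_count_tie_events_zero_and_random(rng):
    ev = count_tie_events(TransitionTable(np.zeros((3, 3), dtype=int)))
    assert ev == EventCounts(0, 0, 0, 0)
    assert ev.pct_changed is None
    for _ in range(20):
        c = rng.integers(0, 50, size=(3, 3))
        ev = count_tie_events(TransitionTable(c, n_reversals=0))
        off = sum(int(c[i, j]) for i in range(3) for j in range(3) if i != j)
        assert ev.n_changed == off


def test_degree_summary_small_examples():
    panel = make_panel([("a", "b", 1)], n_exams=1, actors=["a", "b", "c", "d"])
    ds = degree_summary(panel).to_frame()
    assert ds.loc["prop_0", 1] == 0.75
    assert ds.loc["prop_1", 1] == 0.25
    assert ds.loc["prop_2plus", 1] == 0.0
    assert ds.loc["mean_degree", 1] == 0.25
    # actor naming two alters counts once in the 2+ row, twice in the mean
    panel2 = make_panel([("a", "b", 1), ("a", "c", 1)], n_exams=1,
                        actors=["a", "b", "c", "d"])
    ds2 = degree_summary(panel2).to_frame()
    assert ds2.loc["prop_2plus", 1] == 0.25
    assert ds2.loc["mean_degree", 1] == 0.5


def test_degree_summary_properties(rng):
    panel = random_panel(rng)
    ds = degree_summary(panel).to_frame()
    props = ds.loc[["prop_0", "prop_1", "prop_2plus"]].sum()
    assert np.allclose(props, 1.0, atol=1e-12)
    for t in panel.exams:
        n_present = sum(panel.present(a, t) for a in panel.actors)
        n_ties = len(panel.ties(t))
        assert ds.loc["mean_degree", t] == pytest.approx(n_ties / n_present)
    with pytest.raises(ValueError):
        degree_summary(panel, "bogus")


def test_risk_sets_tie_then_absent():
    panel = make_panel([("a", "b", 1), ("a", "b", 2)], n_exams=3)
    diss, form = extract_risk_sets(panel)
    d = diss[(diss.ego == "a") & (diss.alter == "b")]
    assert list(d.exam) == [2, 3]
    assert list(d.outcome) == [0, 1]  # persisted, then dissolved


def test_risk_sets_exclude_missed_exam_rows():
    panel = make_panel([("a", "b", 1)], n_exams=3, presence_off=[("a", 2)])
    diss, form = extract_risk_sets(panel)
    both = pd.concat([diss, form])
    ab = both[(both.ego == "a") | (both.alter == "a")]
    # outcome at t=2 unobserved; lag missing at t=3: no rows at either exam
    assert not set(ab.exam) & {2, 3}
    # with gap_lag, the exam-1 state supplies the lag for t=3
    diss_g, form_g = extract_risk_sets(panel, gap_lag=True)
    both_g = pd.concat([diss_g, form_g])
    assert 3 in set(both_g[(both_g.ego == "a") & (both_g.alter == "b")].exam)


def test_risk_sets_partition_observed_intervals(rng):
    for _ in range(5):
        panel = random_panel(rng)
        pairs = all_pairs(panel)
        diss, form = extract_risk_sets(panel, pairs=pairs)
        expected = 0
        for (i, j) in pairs:
            for t0, t1 in zip(panel.exams[:-1], panel.exams[1:]):
                if panel.y(i, j, t0) is not None and panel.y(i, j, t1) is not None:
                    expected += 1
        assert len(diss) + len(form) == expected


def test_interval_transition_counts_examples():
    panel = make_panel([("a", "b", 4), ("a", "b", 5), ("a", "b", 6), ("a", "b", 7)],
                       n_exams=7)
    per, gap = interval_transition_counts(panel)
    assert list(per) == [0, 0, 1, 0, 0, 0]
    assert gap == 0
    # observed 1 at exam 2, missing at exam 3, 0 at exam 4 -> one gap transition
    panel2 = make_panel([("a", "b", 2)], n_exams=4, presence_off=[("b", 3)])
    per2, gap2 = interval_transition_counts(panel2)
    assert list(per2) == [1, 0, 0]  # formed between exams 1 and 2
    assert gap2 == 1


def test_interval_transition_counts_match_enumeration(rng):
    panel = random_panel(rng, n_actors=8, n_exams=5)
    pairs = all_pairs(panel)
    per, gap = interval_transition_counts(panel, pairs=pairs)
    total = 0
    for (i, j) in pairs:
        obs = [(t, panel.y(i, j, t)) for t in panel.exams if panel.y(i, j, t) is not None]
        total += sum(1 for (t0, v0), (t1, v1) in zip(obs[:-1], obs[1:]) if v0 != v1)
    assert per.sum() + gap == total


def test_tie_panel_validation():
    with pytest.raises(ValueError):
        make_panel([("a", "a", 1)], n_exams=1)
    with pytest.raises(ValueError):
        TiePanel(pd.DataFrame({"ego_id": ["a"], "alter_id": ["b"], "exam": [2]}),
                 exams=[1])
    panel = make_panel([("a", "b", 1)], n_exams=2)
    with pytest.raises(ValueError):
        panel.y("a", "a", 1)
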