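"""Dyadic predictor construction, design assembly and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepnet.glmm import CrossedGLMMData, fit_laplace
from sepnet.panel import extract_risk_sets
from sepnet.predictors import (TraitSpec, assemble_design, binary_predictors,
                               continuous_predictors, control_predictors,
                               dynamic_reciprocity, sgn, standardize_columns)

from conftest import make_actor_table, make_panel


def test_continuous_predictors_examples():
    p = continuous_predictors(25.0, 20.0)
    assert (p.abs_diff, p.dir_sign, p.signed_diff, p.avg) == (5.0, 1.0, 5.0, 22.5)
    # sgn(0) = -1 by convention, but the signed difference is still 0
    p0 = continuous_predictors(20.0, 20.0)
    assert (p0.abs_diff, p0.dir_sign, p0.signed_diff, p0.avg) == (0.0, -1.0, 0.0, 20.0)
    ind = continuous_predictors(18.0, 20.0, dir_coding="indicator")
    assert ind.dir_sign == 0.0
    with pytest.raises(ValueError):
        continuous_predictors(1.0, 2.0, dir_coding="bogus")


@given(st.floats(-100, 100), st.floats(-100, 100))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_signed_diff_identity_and_swap(x_i, x_j):
    p = continuous_predictors(x_i, x_j)
    q = continuous_predictors(x_j, x_i)
    assert p.signed_diff == pytest.approx(x_i - x_j, abs=1e-12)
    assert p.abs_diff == q.abs_diff
    assert p.avg == q.avg
    if x_i != x_j:
        assert p.signed_diff == -q.signed_diff
        assert p.dir_sign == -q.dir_sign


def test_binary_predictors_truth_table():
    for b_i in (0, 1):
        for b_j in (0, 1):
            p = binary_predictors(b_i, b_j)
            expected = {(1, 0): (1, 0, 0), (0, 1): (0, 1, 0),
                        (1, 1): (0, 0, 1), (0, 0): (0, 0, 0)}[(b_i, b_j)]
            assert (p.ego_only, p.alter_only, p.both) == expected
            assert p.ego_only + p.alter_only + p.both <= 1
    with pytest.raises(ValueError):
        binary_predictors(2, 0)


def test_control_predictors_examples_and_symmetry(rng):
    c = control_predictors(40.0, 44.0, 0.0, 0.0)
    assert (c.age_diff, c.age_avg, c.both_female, c.both_male) == (4.0, 42.0, 1.0, 0.0)
    mixed = control_predictors(30.0, 30.0, 1.0, 0.0)
    assert mixed.both_male == 0.0 and mixed.both_female == 0.0
    assert mixed.geo_sep_lag is None and mixed.edu_diff is None
    for _ in range(25):
        a_i, a_j = rng.normal(40, 10, 2)
        m_i, m_j = rng.integers(0, 2, 2).astype(float)
        c1 = control_predictors(a_i, a_j, m_i, m_j)
        c2 = control_predictors(a_j, a_i, m_j, m_i)
        for f in ("age_diff", "age_avg", "both_male", "both_female"):
            assert getattr(c1, f) == pytest.approx(getattr(c2, f))


def test_dynamic_reciprocity_cases():
    assert dynamic_reciprocity(1, 1).persisted == 1
    assert dynamic_reciprocity(0, 1).formed == 1
    assert dynamic_reciprocity(1, 0).dissolved == 1
    base = dynamic_reciprocity(0, 0)
    assert (base.persisted, base.formed, base.dissolved) == (0, 0, 0)


def _toy_design(trait_exams=None, reciprocity="static_lag"):
    panel = make_panel([("a", "b", 1), ("a", "b", 2), ("b", "a", 2)], n_exams=3)
    actors = make_actor_table(panel)
    diss, form = extract_risk_sets(panel)
    spec = TraitSpec("bmi", exams=trait_exams)
    return assemble_design(pd.concat([diss, form], ignore_index=True), actors,
                           [spec], panel=panel, reciprocity=reciprocity)


def test_assemble_design_toy_panel():
    design, meta = _toy_design()
    assert meta["n_dropped_missing"] == 0
    assert set(meta["trait_columns"]) == {"bmi_abs", "bmi_dir", "bmi_dirxabs", "bmi_avg"}
    assert (design["bmi_abs"] >= 0).all()
    assert "lag_inbound" in design.columns
    # at most one binary indicator active per trait per row
    d2, m2 = _toy_design(reciprocity="dynamic_3component")
    active = d2[["inbound_persisted", "inbound_formed", "inbound_dissolved"]].sum(axis=1)
    assert (active <= 1).all()


def test_assemble_design_availability_window():
    panel = make_panel([(f"a{k}", f"b{k}", t) for k in range(3) for t in (5, 6, 7)],
                       n_exams=7)
    actors = make_actor_table(panel)
    diss, _ = extract_risk_sets(panel)
    # trait measured only at exams 5-7: predictors lag one exam, so rows
    # survive only for outcomes at t in {6, 7}
    design, meta = assemble_design(diss, actors, [TraitSpec("bmi", exams=(5, 6, 7))],
                                   panel=panel)
    assert set(design["exam"]) == {6, 7}
    assert meta["n_dropped_missing"] == len(diss) - len(design)


def test_assemble_design_counts_dropped_rows(rng):
    panel = make_panel([("a", "b", t) for t in (1, 2, 3)]
                       + [("b", "c", 2), ("c", "a", 3)], n_exams=3)
    actors = make_actor_table(panel)
    # knock out one actor-exam trait value
    actors.panel.loc[(actors.panel.actor_id == "b") & (actors.panel.exam == 1),
                     "bmi"] = np.nan
    diss, form = extract_risk_sets(panel)
    rows = pd.concat([diss, form], ignore_index=True)
    design, meta = assemble_design(rows, actors, [TraitSpec("bmi")], panel=panel)
    involves_b_at_lag1 = ((rows.ego == "b") | (rows.alter == "b")) & (rows.exam == 2)
    assert meta["n_dropped_missing"] == int(involves_b_at_lag1.sum())
    assert len(design) == len(rows) - meta["n_dropped_missing"]
    with pytest.raises(KeyError):
        assemble_design(rows, actors, [TraitSpec("nope")], panel=panel)


def test_standardize_two_point_and_idempotence():
    df = pd.DataFrame({"x": [1.0, 3.0]})
    out, scale = standardize_columns(df, ["x"])
    # ddof=1 convention: SD of (1, 3) is sqrt(2)
    assert np.allclose(out["x"], [-np.sqrt(0.5), np.sqrt(0.5)])
    assert scale["x"] == (2.0, pytest.approx(np.sqrt(2.0)))
    twice, _ = standardize_columns(out, ["x"])
    assert np.allclose(twice["x"], out["x"], atol=1e-12)
    with pytest.raises(ValueError, match="const"):
        standardize_columns(pd.DataFrame({"const": [1.0, 1.0]}), ["const"])


def test_standardized_coefficients_back_transform(rng):
    """Fixed-effects logistic fit on standardized columns maps back to the
    unstandardized fit through the recorded scaling constants."""
    n = 400
    x = rng.normal(3.0, 2.0, n)
    z = rng.normal(-1.0, 0.5, n)
    lin = -0.5 + 0.8 * x - 0.6 * z
    y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
    df = pd.DataFrame({"x": x, "z": z})
    std, scale = standardize_columns(df, ["x", "z"])
    senders = np.zeros(n, dtype=int)
    raw = fit_laplace(CrossedGLMMData(y, np.column_stack([np.ones(n), x, z]),
                                      senders, senders, ["c", "x", "z"]),
                      fix_sigma=0.0, fix_tau=0.0)
    stdf = fit_laplace(CrossedGLMMData(y, np.column_stack([np.ones(n), std.x, std.z]),
                                       senders, senders, ["c", "x", "z"]),
                       fix_sigma=0.0, fix_tau=0.0)
    for col in ("x", "z"):
        back = stdf.params.beta[col] / scale[col][1]
        assert back == pytest.approx(raw.params.beta[col], abs=1e-6)


def test_geo_controls_from_pairwise_table():
    panel = make_panel([("a", "b", 1), ("a", "b", 2), ("a", "b", 3)], n_exams=3)
    actors = make_actor_table(panel)
    geo = pd.DataFrame({"actor_id_1": ["a", "a", "a"], "actor_id_2": ["b", "b", "b"],
                        "exam": [1, 2, 3], "distance": [10.0, 4.0, 7.0]})
    diss, _ = extract_risk_sets(panel)
    design, meta = assemble_design(diss, actors, [TraitSpec("bmi")], panel=panel,
                                   controls=("age", "gender", "geo"), geo_table=geo,
                                   geo_change=True)
    row = design[(design.ego == "a") & (design.exam == 3)].iloc[0]
    assert row["geo_sep_lag"] == 4.0                 # separation at t-1
    assert row["geo_sep_change"] == 3.0              # |geo(t) - geo(t-1)|
    assert {"geo_sep_lag", "geo_sep_change"} <= set(meta["control_columns"])
    with pytest.raises(ValueError, match="distance table"):
        assemble_design(diss, actors, [TraitSpec("bmi")], panel=panel,
                        controls=("geo",))


def test_sgn_convention():
    assert sgn(2.0) == 1.0 and sgn(-0.1) == -1.0 and sgn(0.0) == -1.0
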