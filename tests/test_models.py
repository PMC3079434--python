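"""Separable model assembly: outcomes, universes, variants."""

import numpy as np
import pandas as pd
import pytest

from sepnet.models import (ModelConfig, build_dissolution_dataset,
                           build_formation_dataset, double_lag_variant,
                           fit_battery, fit_separable, trait_time_interaction_variant)
from sepnet.panel import extract_risk_sets
from sepnet.predictors import TraitSpec
from sepnet.sampling import INTERCEPT_CAVEAT, SamplerConfig
from sepnet.simulate import SimConfig, SideParams, simulate_panel

from conftest import make_actor_table, make_panel


BASE = ModelConfig(traits=(TraitSpec("bmi"),))
# minimal configuration for toy panels too small to support controls
TOY = ModelConfig(traits=(TraitSpec("bmi"),), controls=(), reciprocity="none",
                  standardize=False)


def _filler_ties(n_dyads=8, exams=(1, 2, 3)):
    """Extra non-overlapping dyads so toy designs have full column rank."""
    rows = []
    for k in range(n_dyads):
        e, a = f"u{k}", f"v{k}"
        for t in exams[: 1 + k % len(exams)]:
            rows.append((e, a, t))
    return rows


def test_dissolution_outcomes_follow_tie_history():
    # tie present at exams 1-3, gone at 4: outcomes (0, 0, 1) at t = 2, 3, 4
    panel = make_panel([("a", "b", 1), ("a", "b", 2), ("a", "b", 3),
                        ("b", "c", 1)] + _filler_ties(8, (1, 2, 3)), n_exams=4)
    actors = make_actor_table(panel)
    data, info = build_dissolution_dataset(panel, actors, TOY)
    design = info["design"]
    ab = design[(design.ego == "a") & (design.alter == "b")].sort_values("exam")
    assert list(ab.exam) == [2, 3, 4]
    assert list(ab.outcome) == [0, 0, 1]
    assert info["reference_exam"] == 2
    assert "exam_2" not in data.column_names and "exam_3" in data.column_names


def test_missing_trait_drops_row_and_is_logged():
    panel = make_panel([("a", "b", 1), ("a", "b", 2), ("a", "b", 3)]
                       + _filler_ties(8, (1, 2)), n_exams=3)
    actors = make_actor_table(panel)
    actors.panel.loc[(actors.panel.actor_id == "b") & (actors.panel.exam == 1),
                     "bmi"] = np.nan
    _data, info = build_dissolution_dataset(panel, actors, TOY)
    assert info["n_dropped_missing"] == 1
    assert info["n_rows"] == info["n_risk_rows"] - 1


def test_tie_level_event_totals_match_enumeration():
    sim = simulate_panel(SimConfig(n_actors=120, p_missing=0.0), seed=4)
    panel = sim.panel
    d_data, _ = build_dissolution_dataset(panel, sim.actors,
                                          ModelConfig(traits=(TraitSpec("bmi"),)))
    f_data, _ = build_formation_dataset(panel, sim.actors,
                                        ModelConfig(traits=(TraitSpec("bmi"),)),
                                        pairs=sim.pairs)
    n_dissolved = n_formed = 0
    for (i, j) in sim.pairs:
        for t0, t1 in zip(panel.exams[:-1], panel.exams[1:]):
            y0, y1 = panel.y(i, j, t0), panel.y(i, j, t1)
            if y0 is None or y1 is None:
                continue
            n_dissolved += int(y0 == 1 and y1 == 0)
            n_formed += int(y0 == 0 and y1 == 1)
    assert int(d_data.outcome.sum()) == n_dissolved
    assert int(f_data.outcome.sum()) == n_formed


def test_formation_toy_and_control_dyads_all_zero():
    panel = make_panel([("a", "b", 1), ("a", "c", 3), ("a", "b", 2), ("a", "b", 3)]
                       + _filler_ties(6, (1, 2, 3)), n_exams=3)
    actors = make_actor_table(panel)
    data, info = build_formation_dataset(panel, actors, TOY)
    design = info["design"]
    formed = design[design.outcome == 1]
    assert list(zip(formed.ego, formed.alter, formed.exam)) == [("a", "c", 3)]
    # sampled control dyads are always-null by construction: only 0 outcomes
    report = {"controls": [("a", "z1"), ("b", "z2")], "k": 1, "seed": 0,
              "cases": [("a", "b")], "chosen_endpoints": ["a", "b"],
              "warnings": [INTERCEPT_CAVEAT]}
    base_rows = [("a", "b", 1), ("a", "b", 2), ("a", "b", 3)] + _filler_ties(6, (1, 2, 3))
    roster = sorted({x for (e, al, _t) in base_rows for x in (e, al)}) + ["z1", "z2"]
    panel2 = make_panel(base_rows, n_exams=3, actors=roster)
    actors2 = make_actor_table(panel2)
    data2, info2 = build_formation_dataset(panel2, actors2, TOY, sampler_report=report)
    design2 = info2["design"]
    ctrl = design2[design2.alter.isin(["z1", "z2"]) | design2.ego.isin(["z1", "z2"])]
    assert len(ctrl) > 0 and (ctrl.outcome == 0).all()
    assert INTERCEPT_CAVEAT in info2["warnings"]


def test_separability_of_the_two_fits():
    sim = simulate_panel(SimConfig(n_actors=150), seed=9)
    cfg = ModelConfig(traits=(TraitSpec("bmi"),), reciprocity="none")
    both = fit_separable(sim.panel, sim.actors, cfg, formation_pairs=sim.pairs,
                         fix_sigma=0.0)
    d_data, _ = build_dissolution_dataset(sim.panel, sim.actors, cfg)
    from sepnet.glmm import fit_laplace
    alone = fit_laplace(d_data, fix_sigma=0.0)
    assert np.allclose(both.dissolution.params.beta.to_numpy(),
                       alone.params.beta.to_numpy(), atol=1e-12)


def test_lag_inbound_all_zero_is_dropped_with_warning():
    # one-way ties only: no inbound nominations exist anywhere
    panel = make_panel([("a", "b", t) for t in (1, 2, 3)]
                       + _filler_ties(8, (1, 2)), n_exams=3)
    actors = make_actor_table(panel)
    cfg = ModelConfig(traits=(TraitSpec("bmi"),), controls=(), standardize=False)
    data, info = build_dissolution_dataset(panel, actors, cfg)
    assert "lag_inbound" not in data.column_names
    assert any("lag_inbound" in w for w in info["warnings"])


def test_dynamic_reciprocity_replaces_single_lag():
    # strong positive reciprocity so mutual dyads actually occur
    sim = simulate_panel(SimConfig(
        n_actors=300,
        formation=SideParams(intercept=-5.88, lag_inbound=3.0, tau=0.686)), seed=5)
    cfg = ModelConfig(traits=(TraitSpec("bmi"),), reciprocity="dynamic_3component",
                      standardize=False)
    data, info = build_dissolution_dataset(sim.panel, sim.actors, cfg)
    cols = set(data.column_names)
    assert "lag_inbound" not in cols
    # the three-component decomposition replaces the single lag term
    # (all-zero components are dropped with a warning, like the static lag)
    present = {"inbound_persisted", "inbound_formed", "inbound_dissolved"} & cols
    dropped = {"inbound_persisted", "inbound_formed", "inbound_dissolved"} - cols
    assert present
    for c in dropped:
        assert any(c in w for w in info["warnings"])


def test_double_lag_restricts_to_late_exams():
    panel = make_panel([("a", "b", t) for t in (1, 2, 3)]
                       + _filler_ties(24, (1, 2, 3)), n_exams=3)
    actors = make_actor_table(panel, noise=8.0)
    cfg = double_lag_variant(TOY)
    assert cfg.double_lag
    data, info = build_dissolution_dataset(panel, actors, cfg)
    assert set(info["design"].exam) == {3}
    assert any(c.endswith("_lag2") for c in data.column_names)
    # row counts shrink exactly by the rows lacking a t-2 predictor
    single, sinfo = build_dissolution_dataset(panel, actors, TOY)
    lacking = (sinfo["design"]["exam"] - 2 < 1).sum()
    assert len(info["design"]) == len(sinfo["design"]) - lacking


def test_trait_exam_interaction_columns():
    sim = simulate_panel(SimConfig(n_actors=120), seed=6)
    cfg = trait_time_interaction_variant(
        ModelConfig(traits=(TraitSpec("bmi"),), standardize=False), "bmi")
    data, info = build_dissolution_dataset(sim.panel, sim.actors, cfg)
    design = info["design"]
    ref = info["reference_exam"]
    # interaction column equals the elementwise product of its factors
    assert np.allclose(design["bmi_abs_x_exam"],
                       design["bmi_abs"] * (design["exam"] - ref))
    with pytest.raises(KeyError):
        trait_time_interaction_variant(ModelConfig(traits=(TraitSpec("bmi"),)), "nope")
    # single-interval panel: interaction inestimable
    panel = make_panel([("a", "b", 1), ("a", "b", 2), ("c", "a", 1)], n_exams=2)
    actors = make_actor_table(panel)
    with pytest.raises(ValueError, match="interaction"):
        build_dissolution_dataset(panel, actors, cfg)


def test_standardization_is_per_dataset():
    sim = simulate_panel(SimConfig(n_actors=150), seed=8)
    cfg = ModelConfig(traits=(TraitSpec("bmi"),))
    _d, dinfo = build_dissolution_dataset(sim.panel, sim.actors, cfg)
    _f, finfo = build_formation_dataset(sim.panel, sim.actors, cfg, pairs=sim.pairs)
    assert dinfo["scale"]["bmi_abs"] != finfo["scale"]["bmi_abs"]
    for info in (dinfo, finfo):
        design = info["design"]
        assert abs(design["bmi_abs"].mean()) < 1e-10
        assert abs(design["bmi_abs"].std(ddof=1) - 1) < 1e-10


def test_fit_battery_groups_traits():
    sim = simulate_panel(SimConfig(n_actors=200), seed=12)
    specs = (TraitSpec("bmi"), TraitSpec("smoker", kind="binary"))
    fits = fit_battery(sim.panel, sim.actors, specs,
                       base_config=ModelConfig(reciprocity="none"),
                       joint_groups=[("bmi", "smoker")],
                       formation_pairs=sim.pairs, fix_sigma=0.0)
    assert set(fits) == {"bmi+smoker"}
    cols = set(fits["bmi+smoker"].dissolution.params.beta.index)
    assert {"bmi_abs", "smoker_both"} <= cols
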