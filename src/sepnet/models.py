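"""The separable tie-dissolution and tie-formation models.

Conditional on the state of a directed tie at the previous exam, two
independent crossed random-effects logistic regressions are fit:

* the *dissolution* model, over directed ties present at ``t - 1``
  (outcome 1 = the tie dissolved by exam ``t``), and
* the *formation* model, over directed null pairs at ``t - 1`` within the
  case/control dyad universe (outcome 1 = the tie formed by exam ``t``).

Each side has its own fixed effects (intercept, exam dummies with the first
modeled exam as reference, the lagged inbound-tie term or its dynamic
three-component decomposition, lagged trait predictors, lagged controls)
and its own sender/receiver random-effect SDs.  Predictor columns are
standardized per model dataset, never across the two sides, so that
coefficients are comparable within a fit.  Data from the first exam only
ever supply predictors, never outcomes.

Sensitivity variants: a double-lag configuration adds the key predictors
evaluated at ``t - 2`` (under the Markov generative law their coefficients
should be null), and a trait-by-exam interaction tests drift of a trait
effect over waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .glmm import CrossedGLMMData, GLMMFit, fit_laplace
from .panel import ActorTable, TiePanel, extract_risk_sets
from .predictors import TraitSpec, assemble_design, standardize_columns
from .sampling import INTERCEPT_CAVEAT, SamplerConfig, sample_null_controls

__all__ = [
    "ModelConfig",
    "SeparableFit",
    "build_dissolution_dataset",
    "build_formation_dataset",
    "fit_separable",
    "fit_battery",
    "double_lag_variant",
    "trait_time_interaction_variant",
]


@dataclass(frozen=True)
class ModelConfig:
    """Configuration shared by the two sides of a separable fit."""

    traits: tuple[TraitSpec, ...] = ()
    reciprocity: str = "static_lag"          # or "dynamic_3component" / "none"
    double_lag: bool = False
    trait_by_exam: str | None = None         # trait name, or None
    controls: tuple[str, ...] = ("age", "gender")
    standardize: bool = True
    standardize_binary: bool = True
    dir_coding: str = "sign"
    gap_lag: bool = False

    def __post_init__(self):
        object.__setattr__(self, "traits", tuple(self.traits))
        if self.reciprocity not in ("static_lag", "dynamic_3component", "none"):
            raise ValueError(f"unknown reciprocity mode {self.reciprocity!r}")


@dataclass
class SeparableFit:
    """Paired dissolution and formation fits plus dataset accounting."""

    dissolution: GLMMFit
    formation: GLMMFit
    meta: dict = field(default_factory=dict)


def _assemble_side(rows: pd.DataFrame, panel: TiePanel, actors: ActorTable,
                   config: ModelConfig, geo_table=None):
    if rows.empty:
        raise ValueError("empty risk set")
    design, meta = assemble_design(
        rows, actors, config.traits, panel=panel, dir_coding=config.dir_coding,
        controls=config.controls, reciprocity=config.reciprocity,
        double_lag=config.double_lag, geo_table=geo_table)
    if design.empty:
        raise ValueError("no rows left after dropping missing predictors")
    return design, meta


def _to_glmm(design: pd.DataFrame, meta: dict, config: ModelConfig
             ) -> tuple[CrossedGLMMData, dict]:
    design = design.copy()
    warnings_: list[str] = []
    exams = sorted(design["exam"].unique())
    ref_exam = exams[0]
    exam_cols = []
    for t in exams[1:]:
        c = f"exam_{t}"
        design[c] = (design["exam"] == t).astype(float)
        exam_cols.append(c)

    recip_cols = list(meta["reciprocity_columns"])
    for c in list(recip_cols):
        if (design[c] == 0).all():
            recip_cols.remove(c)
            warnings_.append(f"inbound-tie column {c!r} is all zero; dropped")

    trait_cols = list(meta["trait_columns"])
    control_cols = list(meta["control_columns"])

    inter_cols: list[str] = []
    if config.trait_by_exam is not None:
        if len(exams) < 2:
            raise ValueError("trait-by-exam interaction requires >= 2 modeled exams")
        spec = next((s for s in config.traits if s.name == config.trait_by_exam), None)
        if spec is None:
            raise KeyError(f"interaction trait {config.trait_by_exam!r} not in model traits")
        tnum = (design["exam"] - ref_exam).astype(float)
        for c in spec.columns():
            ic = f"{c}_x_exam"
            design[ic] = design[c] * tnum
            inter_cols.append(ic)

    scale: dict = {}
    if config.standardize:
        std_cols = trait_cols + control_cols + inter_cols
        if not config.standardize_binary:
            std_cols = [c for c in std_cols
                        if not set(np.unique(design[c])) <= {0.0, 1.0}]
        design, scale = standardize_columns(design, std_cols)

    x_cols = ["intercept"] + exam_cols + recip_cols + trait_cols + inter_cols + control_cols
    design["intercept"] = 1.0
    data = CrossedGLMMData(
        outcome=design["outcome"].to_numpy(),
        fixed_matrix=design[x_cols].to_numpy(),
        sender_ids=design["ego"].to_numpy(),
        receiver_ids=design["alter"].to_numpy(),
        column_names=x_cols)
    info = dict(meta)
    info.update({"reference_exam": ref_exam, "scale": scale, "warnings": warnings_,
                 "key_columns": trait_cols + inter_cols, "design": design})
    return data, info


def build_dissolution_dataset(panel: TiePanel, actors: ActorTable, config: ModelConfig,
                              pairs: Sequence[tuple] | None = None, geo_table=None
                              ) -> tuple[CrossedGLMMData, dict]:
    """Rows with an outbound tie at the lag exam; outcome 1 = dissolved."""
    diss, _form = extract_risk_sets(panel, pairs=pairs, gap_lag=config.gap_lag)
    design, meta = _assemble_side(diss, panel, actors, config, geo_table)
    return _to_glmm(design, meta, config)


def build_formation_dataset(panel: TiePanel, actors: ActorTable, config: ModelConfig,
                            sampler_report: dict | None = None,
                            pairs: Sequence[tuple] | None = None, geo_table=None
                            ) -> tuple[CrossedGLMMData, dict]:
    """Rows with a null outbound tie at the lag exam; outcome 1 = formed.

    The dyad universe is the ever-non-null "case" dyads plus, when a
    sampler report is supplied, its always-null control dyads (both
    directions of each).  ``pairs`` overrides the universe entirely (e.g.
    the full candidate universe of a synthetic panel).
    """
    if pairs is None:
        universe = panel.ever_tied_pairs()
        if sampler_report is not None:
            for (a, b) in sampler_report["controls"]:
                universe.extend([(a, b), (b, a)])
    else:
        universe = list(pairs)
    _diss, form = extract_risk_sets(panel, pairs=universe, gap_lag=config.gap_lag)
    design, meta = _assemble_side(form, panel, actors, config, geo_table)
    data, info = _to_glmm(design, meta, config)
    if sampler_report is not None:
        info["warnings"] = info["warnings"] + [INTERCEPT_CAVEAT]
        info["sampler"] = {k: sampler_report[k] for k in ("k", "seed")}
    return data, info


def fit_separable(panel: TiePanel, actors: ActorTable, config: ModelConfig,
                  sampler_config: SamplerConfig | None = None,
                  formation_pairs: Sequence[tuple] | None = None,
                  geo_table=None, **fit_options) -> SeparableFit:
    """Fit both sides of the separable model.

    When ``sampler_config`` is given, always-null control dyads are sampled
    for the formation side; ``formation_pairs`` instead fixes the formation
    universe explicitly (useful for synthetic panels where the candidate
    universe is known).  Extra keyword arguments pass through to
    :func:`sepnet.glmm.fit_laplace`.
    """
    d_data, d_info = build_dissolution_dataset(panel, actors, config, geo_table=geo_table)
    report = None
    if sampler_config is not None and formation_pairs is None:
        report = sample_null_controls(panel, actors, sampler_config)
    f_data, f_info = build_formation_dataset(panel, actors, config,
                                             sampler_report=report,
                                             pairs=formation_pairs, geo_table=geo_table)
    d_fit = fit_laplace(d_data, **fit_options)
    f_fit = fit_laplace(f_data, **fit_options)
    d_fit.warnings.extend(d_info["warnings"])
    f_fit.warnings.extend(f_info["warnings"])
    d_fit.scale = d_info["scale"]
    f_fit.scale = f_info["scale"]
    meta = {"dissolution": {k: d_info[k] for k in ("n_risk_rows", "n_dropped_missing",
                                                   "n_rows", "reference_exam")},
            "formation": {k: f_info[k] for k in ("n_risk_rows", "n_dropped_missing",
                                                 "n_rows", "reference_exam")},
            "key_columns": d_info["key_columns"],
            "designs": {"dissolution": d_info["design"],
                        "formation": f_info["design"]}}
    if report is not None:
        meta["sampler"] = {"k": report["k"], "seed": report["seed"],
                           "n_controls": len(report["controls"])}
    return SeparableFit(dissolution=d_fit, formation=f_fit, meta=meta)


def fit_battery(panel: TiePanel, actors: ActorTable, traits: Sequence[TraitSpec],
                base_config: ModelConfig | None = None,
                joint_groups: Sequence[tuple[str, ...]] = (),
                sampler_config: SamplerConfig | None = None,
                formation_pairs=None, **fit_options) -> dict[str, SeparableFit]:
    """One separable model per trait (traits named in a joint group are fit
    together in a single model), mirroring a summary-table sweep."""
    base = base_config or ModelConfig()
    by_name = {s.name: s for s in traits}
    grouped: list[tuple[str, ...]] = [tuple(g) for g in joint_groups]
    seen = {n for g in grouped for n in g}
    grouped += [(s.name,) for s in traits if s.name not in seen]
    out: dict[str, SeparableFit] = {}
    for group in grouped:
        cfg = replace(base, traits=tuple(by_name[n] for n in group))
        out["+".join(group)] = fit_separable(panel, actors, cfg,
                                             sampler_config=sampler_config,
                                             formation_pairs=formation_pairs,
                                             **fit_options)
    return out


def double_lag_variant(config: ModelConfig) -> ModelConfig:
    """Sensitivity configuration with key predictors also at ``t - 2``."""
    return replace(config, double_lag=True)


def trait_time_interaction_variant(config: ModelConfig, trait: str) -> ModelConfig:
    """Sensitivity configuration with trait-by-exam interaction columns."""
    if trait not in {s.name for s in config.traits}:
        raise KeyError(f"trait {trait!r} is not in the model configuration")
    return replace(config, trait_by_exam=trait)
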