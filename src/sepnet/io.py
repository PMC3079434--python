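"""Readers and writers for the package's plain-text interchange formats.

* nomination edge list: CSV ``ego_id,alter_id,exam`` (one row per directed
  nomination; absence means "no tie" for present actors);
* actor panel: CSV ``actor_id,exam,present,age,...`` with empty fields for
  missing values;
* actor static table: CSV ``actor_id,sex,...`` for time-invariant traits;
* relative pairs: CSV ``actor_id_1,actor_id_2``;
* run configuration: a single YAML file with ``panel``, ``traits``,
  ``model``, ``sampler`` and ``simulate`` blocks.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .panel import ActorTable, TiePanel
from .predictors import TraitSpec
from .models import ModelConfig
from .sampling import SamplerConfig
from .simulate import BinaryTraitProcess, SideParams, SimConfig, TraitProcess

__all__ = [
    "read_panel",
    "read_actor_table",
    "write_panel",
    "write_actor_table",
    "load_config",
    "write_fit_json",
]


def read_panel(edges_path, presence_path=None, exams=None) -> TiePanel:
    edges = pd.read_csv(edges_path, dtype={"ego_id": str, "alter_id": str})
    presence = None
    if presence_path is not None:
        presence = pd.read_csv(presence_path, dtype={"actor_id": str})
    return TiePanel(edges, presence, exams=exams)


def read_actor_table(panel_path, static_path, relatives_path=None,
                     ever_true_traits=()) -> ActorTable:
    """Read the per-exam and static actor tables (and optional kin pairs).

    Traits named in ``ever_true_traits`` are recoded at ingestion so that an
    actor ever observed positive is positive at every exam (the
    'ever left-handed' convention for binary traits that should not flip).
    """
    panel = pd.read_csv(panel_path, dtype={"actor_id": str})
    static = pd.read_csv(static_path, dtype={"actor_id": str})
    relatives = set()
    if relatives_path is not None:
        rel = pd.read_csv(relatives_path, dtype=str)
        relatives = {frozenset((a, b)) for a, b in rel.iloc[:, :2].itertuples(index=False)}
    table = ActorTable(panel=panel, static=static, relatives=relatives)
    for trait in ever_true_traits:
        table.recode_ever_true(trait)
    return table


def write_panel(panel: TiePanel, edges_path, presence_path=None) -> None:
    rows = [(e, a, t) for t in panel.exams for (e, a) in sorted(panel.ties(t), key=str)]
    pd.DataFrame(rows, columns=["ego_id", "alter_id", "exam"]).to_csv(edges_path, index=False)
    if presence_path is not None:
        prows = [(a, t, panel.present(a, t)) for a in panel.actors for t in panel.exams]
        pd.DataFrame(prows, columns=["actor_id", "exam", "present"]).to_csv(
            presence_path, index=False)


def write_actor_table(actors: ActorTable, panel_path, static_path) -> None:
    actors.panel.to_csv(panel_path, index=False)
    actors.static.to_csv(static_path, index=False)


def _trait_specs(block) -> tuple[TraitSpec, ...]:
    specs = []
    for item in block or []:
        specs.append(TraitSpec(
            name=item["name"], kind=item.get("kind", "continuous"),
            time_invariant=bool(item.get("time_invariant", False)),
            exams=tuple(item["exams"]) if item.get("exams") else None))
    return tuple(specs)


def load_config(path) -> dict:
    """Parse the YAML run configuration into package objects.

    Returns a dict with any of the keys ``model`` (:class:`ModelConfig`),
    ``sampler`` (:class:`SamplerConfig`), ``simulate`` (:class:`SimConfig`),
    ``panel`` (paths dict) and ``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {"seed": int(raw.get("seed", 0))}
    if "panel" in raw:
        out["panel"] = raw["panel"]
    model = raw.get("model", {})
    out["model"] = ModelConfig(
        traits=_trait_specs(raw.get("traits")),
        reciprocity=model.get("reciprocity", "static_lag"),
        double_lag=bool(model.get("double_lag", False)),
        trait_by_exam=model.get("trait_by_exam"),
        controls=tuple(model.get("controls", ("age", "gender"))),
        standardize=bool(model.get("standardize", True)),
        standardize_binary=bool(model.get("standardize_binary", True)),
        dir_coding=model.get("dir_coding", "sign"),
        gap_lag=bool(model.get("gap_lag", False)))
    samp = raw.get("sampler")
    if samp is not None:
        out["sampler"] = SamplerConfig(k=int(samp.get("k", 5)),
                                       seed=int(samp.get("seed", out["seed"])),
                                       exclude_relatives=bool(samp.get("exclude_relatives", True)))
    sim = raw.get("simulate")
    if sim is not None:
        kwargs = {}
        for key in ("n_actors", "n_exams", "candidate_set_size"):
            if key in sim:
                kwargs[key] = int(sim[key])
        for key in ("p_tie_exam1", "sex_ratio", "age_mean", "age_sd",
                    "age_increment", "p_missing"):
            if key in sim:
                kwargs[key] = float(sim[key])
        for side in ("dissolution", "formation"):
            if side in sim:
                s = sim[side]
                kwargs[side] = SideParams(
                    intercept=float(s["intercept"]),
                    lag_inbound=float(s.get("lag_inbound", 0.0)),
                    exam_effects={int(k): float(v) for k, v in (s.get("exam_effects") or {}).items()},
                    trait_effects={k: float(v) for k, v in (s.get("trait_effects") or {}).items()},
                    sigma=float(s.get("sigma", 0.0)), tau=float(s.get("tau", 0.0)))
        if "continuous_traits" in sim:
            kwargs["continuous_traits"] = {
                nm: TraitProcess(float(v["mean"]), float(v["sd"]), float(v["autocorr"]))
                for nm, v in sim["continuous_traits"].items()}
        if "binary_traits" in sim:
            kwargs["binary_traits"] = {
                nm: BinaryTraitProcess(float(v["prevalence"]), float(v["persistence"]))
                for nm, v in sim["binary_traits"].items()}
        out["simulate"] = SimConfig(**kwargs)
    return out


def write_fit_json(fit, path) -> None:
    """Serialize a fitted model (params, SEs, vcov, flags) as JSON."""
    payload = {
        "beta": fit.params.beta.to_dict(),
        "se": fit.se.to_dict(),
        "z": fit.z.to_dict(),
        "p_two_tailed": fit.p_two_tailed.to_dict(),
        "sigma": fit.params.sigma,
        "tau": fit.params.tau,
        "vcov": {"columns": list(fit.vcov.columns),
                 "values": fit.vcov.to_numpy().tolist()},
        "loglik_laplace": fit.loglik_laplace,
        "converged": fit.converged,
        "boundary_sigma": fit.boundary_sigma,
        "boundary_tau": fit.boundary_tau,
        "n_rows": fit.n_rows,
        "n_senders": fit.n_senders,
        "n_receivers": fit.n_receivers,
        "warnings": fit.warnings,
        "scale": {k: list(v) for k, v in fit.scale.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
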