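"""Lagged dyadic predictors for the separable tie models.

For a continuous trait ``x`` measured on both members of an ordered pair,
the key-predictor vector is ``(|x_i - x_j|, sgn(x_i - x_j),
sgn(x_i - x_j)|x_i - x_j|, (x_i + x_j)/2)``: the magnitude and direction of
the dissimilarity, their interaction (the signed difference itself), and the
dyad-average level.  ``sgn`` is +1 for a positive difference and -1
otherwise (so sgn(0) = -1).  For a binary trait the vector is the one-hot of
(ego only, alter only, both), with "neither" the reference category.

Controls mirror the same construction for age, sex, geographic separation
and education.  All assembled predictor columns can be standardized to mean
0 / SD 1 (sample SD, ddof=1) so that coefficients are comparable across
predictors; standardization constants are returned for back-transformation.

Every function accepts scalars or aligned numpy arrays, so the same code
path builds design matrices and drives the synthetic network generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "sgn",
    "continuous_predictors",
    "binary_predictors",
    "control_predictors",
    "dynamic_reciprocity",
    "TraitSpec",
    "assemble_design",
    "standardize_columns",
    "ContinuousTraitPredictors",
    "BinaryTraitPredictors",
    "ControlPredictors",
    "DynamicReciprocity",
]


def sgn(x):
    """Sign with the convention sgn(x) = 1 if x > 0 and -1 otherwise."""
    return np.where(np.asarray(x, dtype=float) > 0, 1.0, -1.0)


@dataclass(frozen=True)
class ContinuousTraitPredictors:
    abs_diff: object
    dir_sign: object
    signed_diff: object
    avg: object


@dataclass(frozen=True)
class BinaryTraitPredictors:
    ego_only: object
    alter_only: object
    both: object


@dataclass(frozen=True)
class ControlPredictors:
    age_diff: object
    age_avg: object
    both_male: object
    both_female: object
    geo_sep_lag: object = None
    geo_sep_change: object = None
    edu_diff: object = None
    edu_avg: object = None


@dataclass(frozen=True)
class DynamicReciprocity:
    persisted: object
    formed: object
    dissolved: object


def continuous_predictors(x_i, x_j, dir_coding: str = "sign") -> ContinuousTraitPredictors:
    """Magnitude/direction/interaction/average for a continuous trait.

    ``dir_coding='sign'`` codes the direction as {+1, -1}; ``'indicator'``
    codes "ego bigger" as {1, 0}.  Under the sign coding the interaction
    term equals the signed difference ``x_i - x_j`` exactly.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    diff = x_i - x_j
    s = sgn(diff)
    direction = s if dir_coding == "sign" else (s > 0).astype(float)
    if dir_coding not in ("sign", "indicator"):
        raise ValueError("dir_coding must be 'sign' or 'indicator'")
    return ContinuousTraitPredictors(
        abs_diff=np.abs(diff), dir_sign=direction,
        signed_diff=s * np.abs(diff), avg=(x_i + x_j) / 2.0)


def binary_predictors(b_i, b_j) -> BinaryTraitPredictors:
    """One-hot (ego only, alter only, both); (0, 0) is the reference."""
    b_i = np.asarray(b_i, dtype=float)
    b_j = np.asarray(b_j, dtype=float)
    flat = np.concatenate([np.atleast_1d(b_i).ravel(), np.atleast_1d(b_j).ravel()])
    if not np.isin(flat[~np.isnan(flat)], (0.0, 1.0)).all():
        raise ValueError("binary trait values must be 0/1")
    return BinaryTraitPredictors(
        ego_only=b_i * (1 - b_j), alter_only=(1 - b_i) * b_j, both=b_i * b_j)


def control_predictors(age_i, age_j, male_i, male_j,
                       geo_sep_lag=None, geo_sep_prev=None,
                       edu_i=None, edu_j=None) -> ControlPredictors:
    """Symmetric control predictors for an ordered pair.

    Geographic separation and education are optional; when omitted the
    corresponding fields are ``None`` (flagged unavailable, never
    zero-filled).  ``geo_sep_change`` is the absolute change in separation
    between the lag exam and the exam before it.
    """
    age_i = np.asarray(age_i, dtype=float)
    age_j = np.asarray(age_j, dtype=float)
    male_i = np.asarray(male_i, dtype=float)
    male_j = np.asarray(male_j, dtype=float)
    geo_change = None
    if geo_sep_lag is not None and geo_sep_prev is not None:
        geo_change = np.abs(np.asarray(geo_sep_lag, float) - np.asarray(geo_sep_prev, float))
    return ControlPredictors(
        age_diff=np.abs(age_i - age_j), age_avg=(age_i + age_j) / 2.0,
        both_male=male_i * male_j, both_female=(1 - male_i) * (1 - male_j),
        geo_sep_lag=None if geo_sep_lag is None else np.asarray(geo_sep_lag, float),
        geo_sep_change=geo_change,
        edu_diff=None if edu_i is None else np.abs(np.asarray(edu_i, float) - np.asarray(edu_j, float)),
        edu_avg=None if edu_i is None else (np.asarray(edu_i, float) + np.asarray(edu_j, float)) / 2.0)


def dynamic_reciprocity(y_ji_lag, y_ji_now) -> DynamicReciprocity:
    """Decompose the inbound tie's history into persisted/formed/dissolved.

    The baseline (all three zero) is non-existence of the inbound tie at
    both exams.
    """
    y0 = np.asarray(y_ji_lag, dtype=float)
    y1 = np.asarray(y_ji_now, dtype=float)
    return DynamicReciprocity(persisted=y0 * y1, formed=(1 - y0) * y1,
                              dissolved=y0 * (1 - y1))


@dataclass(frozen=True)
class TraitSpec:
    """A trait entering the key-predictor block.

    ``kind`` is ``'continuous'`` or ``'binary'``; ``exams`` optionally
    restricts availability (e.g. a measure collected only at later waves);
    ``time_invariant`` traits are read from the actor static table.
    """

    name: str
    kind: str = "continuous"
    time_invariant: bool = False
    exams: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")

    def columns(self, dir_coding: str = "sign") -> list[str]:
        if self.kind == "continuous":
            return [f"{self.name}_abs", f"{self.name}_dir",
                    f"{self.name}_dirxabs", f"{self.name}_avg"]
        return [f"{self.name}_ego_only", f"{self.name}_alter_only", f"{self.name}_both"]


def _merge_actor_values(rows: pd.DataFrame, actors, name: str, spec_time_invariant: bool,
                        lag: int, who: str) -> pd.Series:
    """Value of a trait for the `who` ('ego'/'alter') actor at exam - lag."""
    if spec_time_invariant:
        src = actors.static[["actor_id", name]]
        merged = rows.merge(src, how="left", left_on=who, right_on="actor_id")
    else:
        src = actors.panel[["actor_id", "exam", name]].copy()
        src["exam"] = src["exam"] + lag
        merged = rows.merge(src, how="left", left_on=[who, "exam"],
                            right_on=["actor_id", "exam"])
    return merged[name].to_numpy()


def assemble_design(risk_set: pd.DataFrame, actors, traits: Sequence[TraitSpec],
                    panel=None, dir_coding: str = "sign",
                    controls: Sequence[str] = ("age", "gender"),
                    reciprocity: str = "static_lag", double_lag: bool = False,
                    geo_table: pd.DataFrame | None = None, geo_change: bool = False,
                    ) -> tuple[pd.DataFrame, dict]:
    """Build one design row per eligible (ego, alter, exam) risk-set entry.

    Trait and control predictors are evaluated at ``t - 1`` (and also at
    ``t - 2`` when ``double_lag``); the inbound-tie term is either the
    single lag indicator or its three-component dynamic decomposition.
    Rows with any missing required predictor are dropped; the number dropped
    is reported in the returned metadata.

    Returns ``(design, meta)`` where ``design`` has columns ``ego, alter,
    exam, outcome`` plus named predictor columns, and ``meta`` records row
    accounting and the predictor column lists.
    """
    rows = risk_set.copy().reset_index(drop=True)
    trait_cols: list[str] = []
    known = set(actors.panel.columns) | set(actors.static.columns)
    lags = (1, 2) if double_lag else (1,)
    for spec in traits:
        if spec.name not in known:
            raise KeyError(f"unknown trait {spec.name!r}")
        for lag in lags:
            suffix = "" if lag == 1 else "_lag2"
            x_i = _merge_actor_values(rows, actors, spec.name, spec.time_invariant, lag, "ego")
            x_j = _merge_actor_values(rows, actors, spec.name, spec.time_invariant, lag, "alter")
            if spec.exams is not None and not spec.time_invariant:
                in_window = rows["exam"].sub(lag).isin(spec.exams).to_numpy()
                x_i = np.where(in_window, x_i, np.nan)
                x_j = np.where(in_window, x_j, np.nan)
            if spec.kind == "continuous":
                p = continuous_predictors(x_i, x_j, dir_coding=dir_coding)
                block = {f"{spec.name}_abs{suffix}": p.abs_diff,
                         f"{spec.name}_dir{suffix}": p.dir_sign,
                         f"{spec.name}_dirxabs{suffix}": p.signed_diff,
                         f"{spec.name}_avg{suffix}": p.avg}
                # a NaN difference must not silently become a +/-1 direction
                nan = np.isnan(x_i) | np.isnan(x_j)
                for k in block:
                    block[k] = np.where(nan, np.nan, block[k])
            else:
                p = binary_predictors(np.nan_to_num(x_i), np.nan_to_num(x_j))
                nan = np.isnan(x_i) | np.isnan(x_j)
                block = {f"{spec.name}_ego_only{suffix}": np.where(nan, np.nan, p.ego_only),
                         f"{spec.name}_alter_only{suffix}": np.where(nan, np.nan, p.alter_only),
                         f"{spec.name}_both{suffix}": np.where(nan, np.nan, p.both)}
            for k, v in block.items():
                rows[k] = v
            trait_cols.extend(block.keys())

    control_cols: list[str] = []
    if "age" in controls:
        a_i = _merge_actor_values(rows, actors, "age", False, 1, "ego")
        a_j = _merge_actor_values(rows, actors, "age", False, 1, "alter")
        rows["age_diff"] = np.abs(a_i - a_j)
        rows["age_avg"] = (a_i + a_j) / 2.0
        control_cols += ["age_diff", "age_avg"]
    if "gender" in controls:
        m_i = (pd.Series(_merge_actor_values(rows, actors, "sex", True, 1, "ego"))
               .map({"male": 1.0, "female": 0.0, 1: 1.0, 0: 0.0}).to_numpy())
        m_j = (pd.Series(_merge_actor_values(rows, actors, "sex", True, 1, "alter"))
               .map({"male": 1.0, "female": 0.0, 1: 1.0, 0: 0.0}).to_numpy())
        rows["both_male"] = m_i * m_j
        rows["both_female"] = (1 - m_i) * (1 - m_j)
        control_cols += ["both_male", "both_female"]
    if "education" in controls:
        e_i = _merge_actor_values(rows, actors, "education", False, 1, "ego")
        e_j = _merge_actor_values(rows, actors, "education", False, 1, "alter")
        rows["edu_diff"] = np.abs(e_i - e_j)
        rows["edu_avg"] = (e_i + e_j) / 2.0
        control_cols += ["edu_diff", "edu_avg"]
    if "geo" in controls:
        if geo_table is None:
            raise ValueError("'geo' control requested but no pairwise distance table given")
        gt = geo_table.copy()
        gt.columns = [c.lower() for c in gt.columns]
        key = gt[["actor_id_1", "actor_id_2"]].astype(str)
        gt["_pair"] = np.where(key.iloc[:, 0] < key.iloc[:, 1],
                               key.iloc[:, 0] + "|" + key.iloc[:, 1],
                               key.iloc[:, 1] + "|" + key.iloc[:, 0])
        rk = rows[["ego", "alter"]].astype(str)
        rows["_pair"] = np.where(rk["ego"] < rk["alter"],
                                 rk["ego"] + "|" + rk["alter"],
                                 rk["alter"] + "|" + rk["ego"])
        # lagged separation enters the model; the change variable compares
        # the current exam with the preceding one (deliberately endogenous,
        # used only as a sensitivity control)
        for lag, col in ((1, "geo_sep_lag"), (0, "_geo_sep_now")):
            src = gt[["_pair", "exam", "distance"]].copy()
            src["exam"] = src["exam"] + lag
            merged = rows.merge(src, how="left", on=["_pair", "exam"])
            rows[col] = merged["distance"].to_numpy()
        if geo_change:
            rows["geo_sep_change"] = np.abs(rows["_geo_sep_now"] - rows["geo_sep_lag"])
            control_cols += ["geo_sep_lag", "geo_sep_change"]
        else:
            control_cols += ["geo_sep_lag"]
        rows = rows.drop(columns=["_pair", "_geo_sep_now"])

    recip_cols: list[str] = []
    if panel is not None and reciprocity != "none":
        lag_in = np.empty(len(rows))
        now_in = np.empty(len(rows))
        for r, (e, a, t, tl) in enumerate(rows[["ego", "alter", "exam", "lag_exam"]]
                                          .itertuples(index=False)):
            yl = panel.y(a, e, int(tl))
            yn = panel.y(a, e, int(t))
            lag_in[r] = np.nan if yl is None else yl
            now_in[r] = np.nan if yn is None else yn
        if reciprocity == "static_lag":
            rows["lag_inbound"] = lag_in
            recip_cols = ["lag_inbound"]
        elif reciprocity == "dynamic_3component":
            dr = dynamic_reciprocity(lag_in, now_in)
            rows["inbound_persisted"] = dr.persisted
            rows["inbound_formed"] = dr.formed
            rows["inbound_dissolved"] = dr.dissolved
            recip_cols = ["inbound_persisted", "inbound_formed", "inbound_dissolved"]
        else:
            raise ValueError(f"unknown reciprocity mode {reciprocity!r}")

    required = trait_cols + control_cols + recip_cols
    keep = ~rows[required].isna().any(axis=1) if required else pd.Series(True, index=rows.index)
    n_dropped = int((~keep).sum())
    design = rows.loc[keep].reset_index(drop=True)
    meta = {"n_risk_rows": len(rows), "n_dropped_missing": n_dropped,
            "n_rows": len(design), "trait_columns": trait_cols,
            "control_columns": control_cols, "reciprocity_columns": recip_cols}
    return design, meta


def standardize_columns(df: pd.DataFrame, columns: Sequence[str]
                        ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Rescale columns to sample mean 0 and SD 1 (ddof=1).

    Returns the rescaled frame and ``{column: (mean, sd)}`` so fitted
    coefficients can be mapped back to the original scale
    (``beta_raw = beta_std / sd``).  Raises on constant columns, naming
    them.
    """
    out = df.copy()
    scale: dict[str, tuple[float, float]] = {}
    constant = [c for c in columns if df[c].nunique(dropna=True) < 2]
    if constant:
        raise ValueError(f"cannot standardize constant column(s): {constant}")
    for c in columns:
        m = float(df[c].mean())
        s = float(df[c].std(ddof=1))
        out[c] = (df[c] - m) / s
        scale[c] = (m, s)
    return out, scale
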