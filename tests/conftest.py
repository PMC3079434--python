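"""Shared fixtures: small panels and GLMM instances built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sepnet.glmm import CrossedGLMMData
from sepnet.panel import ActorTable, TiePanel


def make_panel(tie_rows, n_exams, presence_off=(), actors=None):
    """Panel from (ego, alter, exam) triples; presence_off is (actor, exam) pairs."""
    edges = pd.DataFrame(tie_rows, columns=["ego_id", "alter_id", "exam"])
    presence = None
    if presence_off:
        presence = pd.DataFrame([(a, t, False) for a, t in presence_off],
                                columns=["actor_id", "exam", "present"])
    return TiePanel(edges, presence, exams=range(1, n_exams + 1), actors=actors)


def random_panel(rng, n_actors=10, n_exams=4, tie_prob=0.08, miss_prob=0.1):
    """A small random panel over the full ordered-pair universe."""
    ids = [f"p{i}" for i in range(n_actors)]
    rows = []
    for t in range(1, n_exams + 1):
        for i in ids:
            for j in ids:
                if i != j and rng.random() < tie_prob:
                    rows.append((i, j, t))
    off = [(a, t) for a in ids for t in range(1, n_exams + 1) if rng.random() < miss_prob]
    edges = pd.DataFrame(rows, columns=["ego_id", "alter_id", "exam"])
    # drop nominations involving absent actors (their status is missing)
    offset = set(off)
    keep = [k for k, (e, a, t) in enumerate(rows)
            if (e, t) not in offset and (a, t) not in offset]
    edges = edges.iloc[keep]
    presence = pd.DataFrame([(a, t, False) for a, t in off],
                            columns=["actor_id", "exam", "present"])
    return TiePanel(edges, presence, exams=range(1, n_exams + 1), actors=ids)


def all_pairs(panel):
    return [(i, j) for i in panel.actors for j in panel.actors if i != j]


def make_actor_table(panel, rng=None, traits=("bmi",), noise=0.3):
    """Complete actor table over a panel's roster, with simple traits."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for a in panel.actors:
        base = {t: 25.0 + 4.0 * rng.standard_normal() for t in traits}
        for t in panel.exams:
            row = {"actor_id": a, "exam": t, "present": panel.present(a, t),
                   "age": 40.0 + t}
            for name in traits:
                row[name] = base[name] + noise * rng.standard_normal()
            rows.append(row)
    static = pd.DataFrame({"actor_id": list(panel.actors),
                           "sex": [("male" if rng.random() < 0.5 else "female")
                                   for _ in panel.actors]})
    return ActorTable(panel=pd.DataFrame(rows), static=static)


def crossed_instance(seed, qs=3, qr=3, n_waves=12, sigma=0.7, tau=0.9,
                     beta=(-0.3, 0.5)):
    """Tiny fully-crossed GLMM instance with known generative parameters."""
    rng = np.random.default_rng(seed)
    rows = [(i, j) for i in range(qs) for j in range(qr) for _ in range(n_waves)]
    s = np.array([x[0] for x in rows])
    r = np.array([x[1] for x in rows])
    n = len(rows)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    th = sigma * rng.standard_normal(qs)
    et = tau * rng.standard_normal(qr)
    lin = X @ np.asarray(beta) + th[s] + et[r]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(float)
    return CrossedGLMMData(y, X, s, r, ["intercept", "x"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
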