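"""Case-control sampling of always-null dyads for the formation analysis.

Fitting the tie-formation model over every ordered pair that could in
principle form a tie is infeasible for sparse networks: almost all pairs
remain null at every exam.  The sampler augments the "case" dyads (pairs
that are non-null at some exam) with ``k`` randomly drawn "control" dyads
per case, each guaranteed null at every exam.  For each case dyad one
endpoint is chosen uniformly at random and partnered with ``k`` eligible
actors: partners must themselves have nominated somebody at some exam
(so that a nomination was at least possible), must not be relatives of the
chosen actor, and the resulting dyad must never have carried a tie.

Because the controls are a sample, the formation-model intercept no longer
reflects the marginal formation rate; a warning to that effect is attached
to the sampler report and surfaced by the model layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import TiePanel

__all__ = [
    "SamplerConfig",
    "sample_null_controls",
    "count_candidate_null_dyads",
    "transition_opportunities",
    "INTERCEPT_CAVEAT",
]

INTERCEPT_CAVEAT = ("formation dataset built by case-control sampling of always-null "
                    "dyads: the intercept does not reflect the marginal formation rate")


@dataclass(frozen=True)
class SamplerConfig:
    """Control ratio and seed for null-dyad sampling."""

    k: int = 5
    seed: int = 0
    exclude_relatives: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("control ratio k must be >= 1")


def sample_null_controls(panel: TiePanel, actors=None, config: SamplerConfig = SamplerConfig(),
                         ) -> dict:
    """Draw ``k`` always-null control dyads per ever-non-null case dyad.

    Deterministic given ``config.seed``.  Within a case actor's partner pool
    sampling is without replacement; a control dyad colliding with a case
    dyad or an already-sampled control is re-drawn.  Raises if a case actor
    has fewer eligible partners than needed.

    Returns a report dict with keys ``controls`` (list of (case_actor,
    partner) pairs), ``cases``, ``k``, ``seed``, ``chosen_endpoints`` and
    ``warnings``.
    """
    rng = np.random.default_rng(config.seed)
    cases = panel.ever_nonnull_dyads()
    if not cases:
        raise ValueError("no ever-non-null case dyads to sample controls for")
    case_set = set(cases)
    relatives = getattr(actors, "relatives", set()) if actors is not None else set()
    static = getattr(actors, "static", None)
    if static is not None and "ever_nominator" in static.columns:
        # flag covers nominations of non-roster contacts, which the edge
        # list cannot show
        nominators = sorted(static.loc[static["ever_nominator"].astype(bool),
                                       "actor_id"], key=str)
    else:
        nominators = sorted(panel.ever_nominators(), key=str)

    ever_partner: dict = {}
    for t in panel.exams:
        for (e, a) in panel.ties(t):
            ever_partner.setdefault(e, set()).add(a)
            ever_partner.setdefault(a, set()).add(e)

    taken: set[frozenset] = set()
    controls: list[tuple] = []
    chosen: list = []
    for dyad in cases:
        pair = sorted(dyad, key=str)
        anchor = pair[int(rng.integers(2))]
        chosen.append(anchor)
        tied_to = ever_partner.get(anchor, set())
        pool = [p for p in nominators
                if p != anchor
                and p not in tied_to
                and frozenset((anchor, p)) not in case_set
                and not (config.exclude_relatives and frozenset((anchor, p)) in relatives)
                and frozenset((anchor, p)) not in taken]
        if len(pool) < config.k:
            raise ValueError(f"actor {anchor!r} has only {len(pool)} eligible "
                             f"control partners, needs {config.k}")
        draw = rng.choice(len(pool), size=config.k, replace=False)
        for ix in draw:
            partner = pool[int(ix)]
            taken.add(frozenset((anchor, partner)))
            controls.append((anchor, partner))
    return {"controls": controls, "cases": [tuple(sorted(d, key=str)) for d in cases],
            "k": config.k, "seed": config.seed, "chosen_endpoints": chosen,
            "warnings": [INTERCEPT_CAVEAT]}


def count_candidate_null_dyads(n_nonnull: int) -> int:
    """Approximate count of dyads that stayed null among the actors involved
    in the ever-non-null dyads: n(n-1)/2 - n, with n the number of non-null
    dyads.  Undefined (negative) below n = 3."""
    n = int(n_nonnull)
    if n < 3:
        raise ValueError("approximation requires at least 3 non-null dyads")
    return n * (n - 1) // 2 - n


def transition_opportunities(n_dyads: int, n_exams: int) -> dict:
    """Dyad- and tie-level transition opportunities contributed by a set of
    dyads observed over ``n_exams`` waves (one opportunity per consecutive
    exam pair; two directed ties per dyad)."""
    if n_exams < 2:
        raise ValueError("need at least 2 exams for a transition")
    dyad_level = int(n_dyads) * (int(n_exams) - 1)
    return {"dyad_level": dyad_level, "tie_level": 2 * dyad_level}
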