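"""Multi-wave directed nomination panels.

A :class:`TiePanel` stores, for each discrete exam wave, the set of directed
"close friend" nominations among a roster of actors together with per-actor
presence flags.  Exams are treated as synchronized waves: every present actor
is observed at the same nominal time, and the directed indicator
``y[i, j, t]`` is missing whenever either endpoint missed exam ``t``.

The module also provides the dyad-level accounting used to describe such a
panel: classification of unordered pairs into null / directional / mutual
states, the 3x3 state-transition table (with the count of direction
reversals), tie-event totals, degree summaries, per-interval transition
counts, and the risk sets feeding the separable dissolution and formation
models.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DyadState",
    "TiePanel",
    "ActorTable",
    "TransitionTable",
    "EventCounts",
    "DegreeSummary",
    "classify_dyad",
    "transition_table",
    "count_tie_events",
    "degree_summary",
    "extract_risk_sets",
    "interval_transition_counts",
]


class DyadState(enum.IntEnum):
    """State of an unordered pair: no tie, one tie, or ties both ways."""

    NULL = 0
    DIRECTIONAL = 1
    MUTUAL = 2


def classify_dyad(y_ij, y_ji):
    """Classify a dyad from its two directed indicators.

    Returns ``None`` (an explicit missing-state signal, never ``NULL``)
    if either indicator is missing.  Symmetric up to direction: both
    ``(1, 0)`` and ``(0, 1)`` map to ``DIRECTIONAL``.
    """
    if y_ij is None or y_ji is None:
        return None
    if not (y_ij in (0, 1) and y_ji in (0, 1)):
        raise ValueError(f"tie indicators must be 0/1, got ({y_ij!r}, {y_ji!r})")
    if y_ij and y_ji:
        return DyadState.MUTUAL
    if y_ij or y_ji:
        return DyadState.DIRECTIONAL
    return DyadState.NULL


class TiePanel:
    """Directed nomination indicators over exam waves.

    Parameters
    ----------
    edges : DataFrame with columns ``ego_id, alter_id, exam``
        One row per directed nomination.  Absence of a row means "no tie"
        for pairs of actors present at that exam.
    presence : DataFrame with columns ``actor_id, exam, present``
        Presence flags.  Actors never listed are assumed present at every
        exam in ``exams``.
    exams : increasing sequence of positive ints, optional
        Defaults to the range spanned by the edge list.
    actors : iterable of ids, optional
        Roster; defaults to the union of ids seen in edges and presence.
    """

    def __init__(self, edges: pd.DataFrame, presence: pd.DataFrame | None = None,
                 exams: Sequence[int] | None = None, actors: Iterable | None = None):
        edges = edges.copy()
        edges.columns = [c.lower() for c in edges.columns]
        required = {"ego_id", "alter_id", "exam"}
        if not required.issubset(edges.columns):
            raise ValueError(f"edge list needs columns {sorted(required)}")
        if (edges["ego_id"] == edges["alter_id"]).any():
            raise ValueError("self-nominations are not allowed")
        if exams is None:
            lo = int(edges["exam"].min()) if len(edges) else 1
            hi = int(edges["exam"].max()) if len(edges) else 1
            exams = range(lo, hi + 1)
        self.exams = tuple(int(t) for t in exams)
        if list(self.exams) != sorted(set(self.exams)) or any(t <= 0 for t in self.exams):
            raise ValueError("exams must be strictly increasing positive integers")
        bad = set(edges["exam"]) - set(self.exams)
        if bad:
            raise ValueError(f"edge rows reference unknown exams {sorted(bad)}")

        ids = set(edges["ego_id"]) | set(edges["alter_id"])
        if presence is not None:
            presence = presence.copy()
            presence.columns = [c.lower() for c in presence.columns]
            ids |= set(presence["actor_id"])
        if actors is not None:
            ids |= set(actors)
        self.actors = tuple(sorted(ids, key=str))
        self._aidx = {a: k for k, a in enumerate(self.actors)}
        self._tidx = {t: k for k, t in enumerate(self.exams)}

        n, T = len(self.actors), len(self.exams)
        self._present = np.ones((n, T), dtype=bool)
        if presence is not None:
            for a, t, p in presence[["actor_id", "exam", "present"]].itertuples(index=False):
                if a in self._aidx and int(t) in self._tidx:
                    self._present[self._aidx[a], self._tidx[int(t)]] = bool(p)

        self._ties: dict[int, set[tuple]] = {t: set() for t in self.exams}
        for e, a, t in edges[["ego_id", "alter_id", "exam"]].itertuples(index=False):
            t = int(t)
            if not (self._present[self._aidx[e], self._tidx[t]]
                    and self._present[self._aidx[a], self._tidx[t]]):
                raise ValueError(f"nomination {e}->{a} at exam {t} involves an absent actor")
            self._ties[t].add((e, a))

    # -- elementary queries -------------------------------------------------

    def present(self, actor, exam: int) -> bool:
        return bool(self._present[self._aidx[actor], self._tidx[exam]])

    def y(self, i, j, t: int):
        """Directed indicator; ``None`` when either endpoint missed exam t."""
        if i == j:
            raise ValueError("y is undefined on the diagonal (no self-ties)")
        if not (self.present(i, t) and self.present(j, t)):
            return None
        return int((i, j) in self._ties[t])

    def ties(self, t: int) -> frozenset:
        return frozenset(self._ties[t])

    @property
    def n_actors(self) -> int:
        return len(self.actors)

    def ever_nominators(self) -> frozenset:
        """Actors who named at least one contact at some exam."""
        return frozenset(e for t in self.exams for (e, _a) in self._ties[t])

    def ever_tied_pairs(self) -> list[tuple]:
        """Ordered pairs (both directions) of every dyad ever non-null."""
        dyads = {frozenset(p) for t in self.exams for p in self._ties[t]}
        out = []
        for d in dyads:
            a, b = sorted(d, key=str)
            out.extend([(a, b), (b, a)])
        return sorted(out, key=lambda p: (str(p[0]), str(p[1])))

    def ever_nonnull_dyads(self) -> list[frozenset]:
        return sorted({frozenset(p) for t in self.exams for p in self._ties[t]},
                      key=lambda d: tuple(sorted(d, key=str)))

    # -- vectorized views ---------------------------------------------------

    def tie_matrix(self, pairs: Sequence[tuple]) -> tuple[np.ndarray, np.ndarray]:
        """Dense (n_pairs, n_exams) views over an ordered-pair universe.

        Returns ``(y, observed)`` int8/bool arrays; ``y`` is only meaningful
        where ``observed`` (both endpoints present).
        """
        npairs, T = len(pairs), len(self.exams)
        y = np.zeros((npairs, T), dtype=np.int8)
        obs = np.zeros((npairs, T), dtype=bool)
        ei = np.fromiter((self._aidx[p[0]] for p in pairs), dtype=np.int64, count=npairs)
        ai = np.fromiter((self._aidx[p[1]] for p in pairs), dtype=np.int64, count=npairs)
        for k, t in enumerate(self.exams):
            obs[:, k] = self._present[ei, k] & self._present[ai, k]
            tied = self._ties[t]
            if tied:
                y[:, k] = np.fromiter(((p in tied) for p in pairs), dtype=np.int8, count=npairs)
        y[~obs] = 0
        return y, obs

    def out_degree(self, t: int) -> dict:
        deg = {a: 0 for a in self.actors if self.present(a, t)}
        for (e, _a) in self._ties[t]:
            deg[e] += 1
        return deg


@dataclass
class ActorTable:
    """Actor covariates: per-exam panel, time-invariant traits, kin pairs.

    ``panel`` has one row per (actor_id, exam) with at least ``present`` and
    ``age``; trait columns are free-form.  ``static`` has one row per actor
    (``sex`` plus any time-invariant traits).  ``relatives`` is a set of
    unordered id pairs excluded from control sampling.
    """

    panel: pd.DataFrame
    static: pd.DataFrame
    relatives: set = field(default_factory=set)

    def __post_init__(self):
        self.panel = self.panel.copy()
        self.static = self.static.copy()
        if self.static["actor_id"].duplicated().any():
            raise ValueError("duplicate actor_id in static table")
        self.relatives = {frozenset(p) for p in self.relatives}
        for p in self.relatives:
            if len(p) != 2:
                raise ValueError("a relative pair must contain two distinct actors")

    def recode_ever_true(self, trait: str) -> None:
        """Recode a binary panel trait to 1 at every exam for any actor ever
        recorded positive (the 'ever left-handed' convention)."""
        ever = self.panel.groupby("actor_id")[trait].transform(lambda s: (s == 1).any())
        self.panel[trait] = np.where(ever, 1.0, self.panel[trait])

    def are_relatives(self, a, b) -> bool:
        return frozenset((a, b)) in self.relatives

    def lagged(self, columns: Sequence[str], exam_offset: int = 1) -> pd.DataFrame:
        """Panel rows re-indexed so that row (actor, t) carries the values
        measured at exam t - exam_offset; used to build lagged predictors."""
        df = self.panel[["actor_id", "exam", *columns]].copy()
        df["exam"] = df["exam"] + exam_offset
        return df


@dataclass
class TransitionTable:
    """3x3 dyad-state transition counts and the direction-reversal count."""

    counts: np.ndarray
    n_reversals: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        D = DyadState.DIRECTIONAL
        if not 0 <= self.n_reversals <= self.counts[D, D]:
            raise ValueError("reversals must be subsumed in directional->directional")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [s.name.capitalize() for s in DyadState]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass(frozen=True)
class EventCounts:
    """Dyad-level tie-event totals derived from a transition table."""

    n_dissolved: int
    n_formed: int
    n_changed: int
    n_total: int

    @property
    def pct_changed(self):
        """Percentage of dyad-intervals whose state changed; ``None`` when
        there are no observed intervals."""
        if self.n_total == 0:
            return None
        return 100.0 * self.n_changed / self.n_total


def transition_table(panel: TiePanel, dyads: Sequence[frozenset] | None = None) -> TransitionTable:
    """Count dyad-state transitions over consecutive exam pairs.

    A dyad-interval enters the table only when both actors are present at
    both endpoints.  A directional->directional pair whose single tie flipped
    direction increments both ``counts[D, D]`` and ``n_reversals``.
    """
    if dyads is None:
        dyads = panel.ever_nonnull_dyads()
    counts = np.zeros((3, 3), dtype=np.int64)
    n_rev = 0
    for d in dyads:
        a, b = sorted(d, key=str)
        for t_prev, t in zip(panel.exams[:-1], panel.exams[1:]):
            y_ab0, y_ba0 = panel.y(a, b, t_prev), panel.y(b, a, t_prev)
            y_ab1, y_ba1 = panel.y(a, b, t), panel.y(b, a, t)
            s0 = classify_dyad(y_ab0, y_ba0)
            s1 = classify_dyad(y_ab1, y_ba1)
            if s0 is None or s1 is None:
                continue
            counts[s0, s1] += 1
            if (s0 is DyadState.DIRECTIONAL and s1 is DyadState.DIRECTIONAL
                    and y_ab1 == 1 - y_ab0 and y_ba1 == 1 - y_ba0):
                n_rev += 1
    return TransitionTable(counts, n_rev)


def count_tie_events(table: TransitionTable) -> EventCounts:
    """Tie-event totals implied by a dyad-state transition table.

    Direction reversals dissolve one tie and form another, so they are added
    to the dissolution, formation, and changed-dyad totals on top of the
    off-diagonal cells.
    """
    c = table.counts
    N, D, M = DyadState.NULL, DyadState.DIRECTIONAL, DyadState.MUTUAL
    r = table.n_reversals
    n_dissolved = int(c[D, N] + c[M, N] + c[M, D]) + r
    n_formed = int(c[N, D] + c[N, M] + c[D, M]) + r
    off_diag = int(c.sum() - np.trace(c))
    return EventCounts(n_dissolved=n_dissolved, n_formed=n_formed,
                       n_changed=off_diag + r, n_total=table.total)


@dataclass
class DegreeSummary:
    """Out-degree distribution by exam: proportions in {0, 1, 2+}, mean
    out-degree among present actors, and the number who missed each exam
    (reported inside the degree-0 row, as flagged)."""

    table: pd.DataFrame  # rows: prop_0, prop_1, prop_2plus, mean_degree, n_missed

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def degree_summary(panel: TiePanel, actor_subset: str = "all") -> DegreeSummary:
    """Out-degree distribution per exam.

    ``actor_subset`` is ``"all"`` or ``"ever-non-null"`` (actors involved in
    a non-null dyad at some exam).  Absent actors are counted in the degree-0
    row (with their count reported separately); the mean degree is the number
    of ties divided by the number of present actors.
    """
    if actor_subset == "all":
        roster = list(panel.actors)
    elif actor_subset in ("ever-non-null", "ever_non_null"):
        involved = {a for t in panel.exams for p in panel.ties(t) for a in p}
        roster = sorted(involved, key=str)
    else:
        raise ValueError("actor_subset must be 'all' or 'ever-non-null'")
    if not roster:
        raise ValueError("empty actor subset")
    cols = {}
    for t in panel.exams:
        deg = panel.out_degree(t)
        deg = {a: d for a, d in deg.items() if a in set(roster)}
        n_missed = sum(1 for a in roster if a not in deg)
        n = len(roster)
        n0 = sum(1 for d in deg.values() if d == 0) + n_missed
        n1 = sum(1 for d in deg.values() if d == 1)
        n2 = sum(1 for d in deg.values() if d >= 2)
        n_ties = sum(deg.values())
        mean = n_ties / len(deg) if deg else 0.0
        cols[t] = [n0 / n, n1 / n, n2 / n, mean, n_missed]
    table = pd.DataFrame(cols, index=["prop_0", "prop_1", "prop_2plus",
                                      "mean_degree", "n_missed"])
    return DegreeSummary(table)


def extract_risk_sets(panel: TiePanel, pairs: Sequence[tuple] | None = None,
                      gap_lag: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split observed directed-tie intervals into the two model risk sets.

    For every ordered pair in the universe and every exam ``t`` at which the
    outcome is observed and the lag state is known:

    * lag tie present  -> a *dissolution* row (outcome 1 = tie dissolved),
    * lag tie absent   -> a *formation* row (outcome 1 = tie formed).

    With ``gap_lag=False`` (default, the strict Markov reading) the lag is
    the state at ``t - 1``; rows whose ``t - 1`` state is unobserved are
    excluded.  With ``gap_lag=True`` the most recent earlier observed exam
    supplies the lag instead.

    Returns ``(dissolution_rows, formation_rows)`` DataFrames with columns
    ``ego, alter, exam, lag_exam, outcome``.
    """
    if pairs is None:
        pairs = panel.ever_tied_pairs()
    pairs = list(pairs)
    diss, form = [], []
    if pairs:
        y, obs = panel.tie_matrix(pairs)
        T = len(panel.exams)
        for k in range(1, T):
            t = panel.exams[k]
            if gap_lag:
                lag_k = np.full(len(pairs), -1)
                for back in range(k - 1, -1, -1):
                    lag_k = np.where((lag_k < 0) & obs[:, back], back, lag_k)
            else:
                lag_k = np.where(obs[:, k - 1], k - 1, -1)
            ok = obs[:, k] & (lag_k >= 0)
            idx = np.nonzero(ok)[0]
            for r in idx:
                lk = int(lag_k[r])
                lag_y = int(y[r, lk])
                row = (pairs[r][0], pairs[r][1], t, panel.exams[lk],
                       int(y[r, k] == 0) if lag_y else int(y[r, k] == 1))
                (diss if lag_y else form).append(row)
    cols = ["ego", "alter", "exam", "lag_exam", "outcome"]
    return (pd.DataFrame(diss, columns=cols), pd.DataFrame(form, columns=cols))


def interval_transition_counts(panel: TiePanel, pairs: Sequence[tuple] | None = None
                               ) -> tuple[pd.Series, int]:
    """Directed-tie status changes per consecutive exam pair, plus the count
    of changes spanning one or more exams with missing tie status.

    Returns ``(per_interval, n_gap)`` where ``per_interval`` is indexed by
    interval labels ``"1-2", "2-3", ...``.
    """
    if pairs is None:
        pairs = panel.ever_tied_pairs()
    pairs = list(pairs)
    T = len(panel.exams)
    per = np.zeros(T - 1, dtype=np.int64)
    n_gap = 0
    if pairs:
        y, obs = panel.tie_matrix(pairs)
        for r in range(len(pairs)):
            ks = np.nonzero(obs[r])[0]
            for a, b in zip(ks[:-1], ks[1:]):
                if y[r, a] != y[r, b]:
                    if b == a + 1:
                        per[a] += 1
                    else:
                        n_gap += 1
    labels = [f"{t0}-{t1}" for t0, t1 in zip(panel.exams[:-1], panel.exams[1:])]
    return pd.Series(per, index=labels, name="tie_transitions"), n_gap
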