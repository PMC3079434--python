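"""Descriptive summaries and the binned empirical-logit diagnostic.

The diagnostic answers "what shape does the transition probability take as
a function of a dyadic difference?": observations are grouped into
equal-count bins by the quantiles of a predictor (ego minus alter trait
difference, say), and each bin's event proportion is plotted on the logit
scale against the bin's mean predictor value.  A V shape in dissolution
(and an inverted V in formation) supports the absolute difference as the
dissimilarity metric.  Degenerate 0 or 100 per cent bins are handled with
the empirical-logit adjustment (events + 0.5) / (count + 1), keeping every
bin finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (TiePanel, count_tie_events, degree_summary,
                    interval_transition_counts, transition_table)

__all__ = ["BinnedLogit", "binned_logit", "describe"]


@dataclass
class BinnedLogit:
    """Per-bin mean predictor value, event proportion, adjusted logit, count."""

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def binned_logit(values, outcomes, n_bins: int = 50, smoother=None) -> BinnedLogit:
    """Empirical-logit diagnostic over predictor-quantile bins.

    ``n_bins`` equal-count bins (ties permitting) are formed from the
    quantiles of ``values``; within each bin the event proportion ``p`` is
    adjusted to ``(events + 0.5) / (count + 1)`` before the logit, so that
    all-event and no-event bins stay plottable.  ``smoother``, if given, is
    a callable ``f(mean_values, logits) -> smoothed_logits`` whose output is
    attached as a cosmetic ``smooth`` column (a lowess overlay, say); it
    plays no role in any inference.
    """
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if values.shape != outcomes.shape:
        raise ValueError("values and outcomes must be aligned")
    if len(values) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations, have {len(values)}")
    bins = pd.qcut(pd.Series(values).rank(method="first"), q=n_bins, labels=False)
    df = pd.DataFrame({"value": values, "outcome": outcomes, "bin": bins})
    g = df.groupby("bin")
    table = pd.DataFrame({
        "mean_value": g["value"].mean(),
        "count": g.size(),
        "events": g["outcome"].sum(),
    })
    table["proportion"] = table["events"] / table["count"]
    p_adj = (table["events"] + 0.5) / (table["count"] + 1.0)
    table["logit"] = np.log(p_adj / (1.0 - p_adj))
    if smoother is not None:
        table["smooth"] = np.asarray(
            smoother(table["mean_value"].to_numpy(), table["logit"].to_numpy()))
    return BinnedLogit(table.reset_index(drop=True))


def describe(panel: TiePanel) -> dict:
    """Descriptive accounting of a nomination panel.

    Returns degree summaries (full roster and ever-non-null subset), the
    dyad-state transition table with its reversal count, the tie-event
    totals, and per-interval plus gap-spanning tie transition counts.
    """
    tt = transition_table(panel)
    events = count_tie_events(tt)
    per_interval, n_gap = interval_transition_counts(panel)
    out = {
        "degree_all": degree_summary(panel, "all"),
        "degree_ever_non_null": degree_summary(panel, "ever-non-null"),
        "transition_table": tt,
        "events": events,
        "interval_tie_transitions": per_interval,
        "gap_tie_transitions": n_gap,
    }
    return out


def describe_text(panel: TiePanel) -> str:
    """Human-readable rendering of :func:`describe`."""
    d = describe(panel)
    tt = d["transition_table"]
    ev = d["events"]
    lines = [
        "Degree distribution by exam (all actors):",
        d["degree_all"].to_frame().round(3).to_string(),
        "",
        "Dyad-state transitions (consecutive exams):",
        tt.to_frame().to_string(),
        f"direction reversals: {tt.n_reversals}",
        "",
        f"ties dissolved: {ev.n_dissolved}   ties formed: {ev.n_formed}",
        f"dyads changed: {ev.n_changed} of {ev.n_total}"
        + (f" ({ev.pct_changed:.2f}%)" if ev.pct_changed is not None else ""),
        "",
        "Directed-tie transitions per interval:",
        d["interval_tie_transitions"].to_string(),
        f"gap-spanning transitions: {d['gap_tie_transitions']}",
    ]
    return "\n".join(lines)
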