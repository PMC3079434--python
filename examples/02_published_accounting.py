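"""Reproduce the published dyad-transition arithmetic.

The framework was developed on the Framingham Heart Study offspring-cohort
close-friend panel, whose raw network is not public.  Its printed
descriptive accounting is, and it exercises the same event arithmetic this
package applies to any panel: feeding the published transition matrix and
reversal count through `count_tie_events` reproduces the published event
totals (648 dissolutions, 568 formations, 1210 changed dyads of 6274,
19.29 per cent), and the published per-interval transition counts sum to
1231 consecutive-exam transitions, 1380 once gap-spanning ones are added.
"""

from sepnet import TransitionTable, count_tie_events
from sepnet import published as pub
from sepnet.sampling import count_candidate_null_dyads, transition_opportunities

table = TransitionTable(pub.TRANSITION_MATRIX, n_reversals=pub.N_REVERSALS)
ev = count_tie_events(table)
print(f"ties dissolved: {ev.n_dissolved}, formed: {ev.n_formed}")
print(f"dyads changed: {ev.n_changed} of {ev.n_total} ({ev.pct_changed:.2f}%)")

consecutive = sum(pub.INTERVAL_TIE_TRANSITIONS)
print(f"consecutive-exam tie transitions: {consecutive}; "
      f"with gap-spanning: {consecutive + pub.GAP_TIE_TRANSITIONS}")

n = pub.N_EVER_NONNULL_DYADS
print(f"approximate always-null candidate dyads among the {n} cases: "
      f"{count_candidate_null_dyads(n)}")
controls = n * pub.CONTROL_RATIO
opp = transition_opportunities(controls, pub.N_EXAMS)
print(f"{controls} sampled controls add {opp['dyad_level']} dyad-level "
      f"({opp['tie_level']} tie-level) transition opportunities")
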