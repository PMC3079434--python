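"""Published accounting for the Framingham Heart Study friendship panel.

The separable-model framework was developed for the close-friend
nomination network recorded on Framingham Heart Study offspring-cohort
tracking sheets over seven exam waves (1971-2003).  The raw network data
are not public, but the study's printed descriptive accounting is, and it
exercises the dyad-transition arithmetic end to end: these constants are
inputs to the worked examples and the reproduction script, not outputs of
this package.
"""

from __future__ import annotations

import numpy as np

#: Dyad-state transition counts over consecutive exams (rows: state at
#: t-1, columns: state at t; order null, directional, mutual).
TRANSITION_MATRIX = np.array([[2520, 505, 5],
                              [553, 2203, 52],
                              [10, 79, 347]], dtype=np.int64)

#: Directional-to-directional transitions in which the single tie flipped
#: direction (each dissolves one directed tie and forms another).
N_REVERSALS = 6

#: Directed-tie status changes between consecutive exam pairs 1-2 ... 6-7.
INTERVAL_TIE_TRANSITIONS = (218, 261, 319, 187, 152, 94)

#: Additional tie status changes observed across one or more exams with
#: missing tie status in between.
GAP_TIE_TRANSITIONS = 149

#: Number of unordered dyads with non-null status at some exam, and the
#: number of exam waves.
N_EVER_NONNULL_DYADS = 1286
N_EXAMS = 7

#: Control-to-case ratio used for the always-null dyad sample.
CONTROL_RATIO = 5

#: Average out-degree by exam for the full offspring cohort.
AVERAGE_DEGREE_BY_EXAM = (0.236, 0.242, 0.246, 0.247, 0.238, 0.230, 0.217)
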