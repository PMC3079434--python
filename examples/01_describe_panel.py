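"""Descriptive accounting of a nomination panel.

Generates a small synthetic seven-wave friendship panel and prints its
degree distribution, the 3x3 dyad-state transition table with the count of
direction reversals, the tie-event totals derived from it, and per-interval
directed-tie transition counts.  The "ties dissolved / formed" lines count
directed nomination events; "dyads changed" counts unordered pairs whose
joint state moved between consecutive exams.
"""

from sepnet import SimConfig, simulate_panel
from sepnet.reporting import describe_text

sim = simulate_panel(SimConfig(n_actors=400), seed=7)
print(describe_text(sim.panel))
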