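"""Case-control sampling of always-null dyads.

The formation model cannot be fit over every pair that might have formed a
tie (almost all pairs never do).  For each ever-connected "case" dyad the
sampler picks one endpoint at random and draws k partners whose dyad stayed
null at every exam, restricted to actors who themselves nominated somebody
and excluding relatives.  The script prints the bookkeeping: k controls per
case and the dyad-level / tie-level transition opportunities they add.
"""

from sepnet import SamplerConfig, SimConfig, simulate_panel
from sepnet.sampling import sample_null_controls, transition_opportunities

sim = simulate_panel(SimConfig(n_actors=300), seed=5)
n_cases = len(sim.panel.ever_nonnull_dyads())
report = sample_null_controls(sim.panel, sim.actors, SamplerConfig(k=5, seed=9))
print(f"{n_cases} case dyads, k=5 -> {len(report['controls'])} control dyads")
opp = transition_opportunities(len(report["controls"]), len(sim.panel.exams))
print(f"controls add {opp['dyad_level']} dyad-level ({opp['tie_level']} "
      f"tie-level) transition opportunities over {len(sim.panel.exams)} waves")
print("note:", report["warnings"][0])
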