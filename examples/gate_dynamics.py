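"""Channel-gate tracing on a Markov-switching trajectory.

The separation of the two gating side chains of the 2b channel switches
between 5 Å (open) and 9 Å (closed) following a two-state Markov chain
with a stationary open probability of 0.4. A gate counts as open when
the side-chain COM distance drops below 7 Å; the recovered fraction-open
matches the generator's ground truth.
"""

import numpy as np

from p450kit.fixtures import make_gate_trajectory
from p450kit.gating import GateDefinition, fraction_open_report, gate_trace

gate = GateDefinition("2b", ("A", 108, "PHE"), ("A", 220, "PHE"), open_threshold=7.0)

traces = {}
for model, p_open in (("apo", 0.6), ("R-warfarin", 0.3)):
    traj, meta = make_gate_trajectory(5000, p_open=p_open, rate=0.2, seed=3)
    trace = gate_trace(traj, gate)
    traces[model] = {"2b": [trace]}
    truth = 100.0 * np.mean(meta["states_open"])
    print(f"{model:11s} stationary p_open = {p_open:.1f}  ->  "
          f"measured {100 * trace.fraction_open:.1f}% open "
          f"(state-sequence truth {truth:.1f}%)")

print("\nPooled per-gate report (percent open):")
print(fraction_open_report(traces).round(1).to_string())
print(
    "\nThe apo/substrate-bound contrast mirrors how substrate binding closes\n"
    "access channels; the measured percentages equal the exact open-state\n"
    "fraction of the generating Markov chain."
)
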