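"""Attribute a target unit's response to its input channels.

For a chosen IT unit, each of the V4 input channels is scored by the
product of (a) the summed 3x3 kernel weights connecting the channel to
the target and (b) the channel's maximal word-selective response inside
the target's receptive field over the unit's 20-stimulus probe set.
Positive products are excitatory inputs, negative inhibitory.
"""

import numpy as np

from ortholens.connectivity import attribute
from ortholens.cornet import build_network, default_spec, record_activations
from ortholens.stimgen import DEFAULT_CANVAS, make_factorial_probe
from ortholens.store import UnitAddress

canvas = DEFAULT_CANVAS.scaled(64)
model = build_network(default_spec(64, (16, 32, 64, 128)), n_out=4, seed=0)

design = make_factorial_probe("o", "x", canvas=canvas)
store = record_activations(
    model, np.stack([s.image for s in design.stimuli]), ("V4",))

target = UnitAddress("IT", 5, 1, 1)
# in a full analysis the mask comes from the selectivity localizer on V4;
# here every unit is admitted so the example runs on an untrained net
mask = np.ones(store.get("V4").shape[1:], dtype=bool)
report = attribute(model, target, "V4", store, mask, probe_design=design)

print(f"target {target}: {len(report.weight_sums)} input channels")
frame = report.to_frame().sort_values("product")
print("\nstrongest inhibitory channels (most negative product):")
print(frame.head(2).round(3).to_string(index=False))
print("\nstrongest excitatory channels:")
print(frame.tail(2).round(3).to_string(index=False))
print("\nweight_sum is the net sign/strength of the kernel; drive is the "
      "channel's best response inside the RF; their product ranks inputs")
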