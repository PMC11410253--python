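"""Effective receptive fields by exact backprojection.

The default architecture processes a 224x224x3 image through four
conv/pool blocks (V1 64x56x56, V2 128x28x28, V4 256x14x14, IT 512x7x7).
Each block's 3x3 padded convolution plus 3x3 stride-2 pool means a
single IT spatial unit sees a 5x5 patch of the V4 output grid.
"""

from ortholens.cornet import (build_network, default_spec,
                              effective_receptive_field, rf_box_side)
from ortholens.store import UnitAddress

model = build_network(default_spec(224), n_out=10, seed=0)
print("grid sizes (post-conv, post-pool):", model.spec.grid_sizes())

for layer, pos, to in (("IT", (3, 3), "V4"), ("IT", (0, 0), "V4"),
                       ("V4", (7, 7), "V2"), ("IT", (3, 3), "V1")):
    unit = UnitAddress(layer, 0, *pos)
    box = effective_receptive_field(model, unit, to)
    print(f"{layer} unit at {pos} -> {to}: box rows {box[0]}-{box[1]}, "
          f"cols {box[2]}-{box[3]} (side {rf_box_side(box)})")
# the central IT unit yields side 5 (the 5x5 region of V4 it can see);
# corner units are clipped at the grid border
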