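# "Simple" seawall tile: one pit type, every dimension fixed, ordered grid.
# 400 x 400 x 60 mm concrete tile with 36 square pits of 32 mm side/depth.
tile: {width: 400, length: 400, thickness: 60}
units: mm
object_types:
  - id: pit
    colour: "#35618f"
    shape: square
    footprint: {kind: fixed, value: 32}
    depth: {kind: fixed, value: 32}
abundances: [1.0]
total_count: 36
arrangement: ordered
buffer: 8
seed: 7
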