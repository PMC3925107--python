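# "Complex" seawall tile: same pit count and the same mean dimensions as the
# simple tile (32 mm), but side and depth drawn from the 8-56 mm lattice in
# 8 mm steps and pits placed at random. Expected surface area matches the
# simple tile's, isolating complexity from area.
tile: {width: 400, length: 400, thickness: 60}
units: mm
object_types:
  - id: pit
    colour: "#8f3561"
    shape: square
    footprint: {kind: discrete-uniform, minimum: 8, maximum: 56, increment: 8}
    depth: {kind: discrete-uniform, minimum: 8, maximum: 56, increment: 8}
abundances: [1.0]
total_count: 36
arrangement: random
buffer: 8
seed: 7
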