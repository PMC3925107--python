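# habtile

Design artificial-substrate tiles with precisely controlled **informational
habitat complexity**, and export them as fabrication-ready files.

Ecologists studying the complexity–biodiversity relationship (and engineers
doing reconciliation work on seawalls and other hard infrastructure) need
substrates whose structural complexity is a *controlled variable* rather
than an accident of construction. `habtile` generates rectangular tile
designs — fields of circular or square vertical-walled pits — where
complexity is manipulated through five variables:

1. number of object types,
2. relative abundance of each type,
3. density (total object count),
4. variability and range of object dimensions, and
5. spatial arrangement (random vs ordered).

Complexity is quantified as information content. For the type-abundance
vector *p* = (p₁, …, p_k) the tile's type entropy is Shannon's

&nbsp;&nbsp;&nbsp;&nbsp;H(X) = −Σᵢ pᵢ log₂ pᵢ  (bits),

reported together with per-dimension size-level counts over the discrete
size lattice {min + j·increment} (log₂ of the count is the per-dimension
entropy under uniform sampling) and the combination count
*components^descriptors* (density to the power of the number of varying
attributes). Entropy comparisons are gated on a `comparable_key`: they are
only meaningful between tiles generated under the same rules — same
arrangement mode, same distribution kinds, no manual edits.

Placement honours physical constraints: every footprint lies fully inside
the tile and every pair of objects keeps at least a user-set edge-to-edge
**buffer**. Random arrangements use random sequential adsorption (dart
throwing, largest footprint first); ordered arrangements use a
deterministic even-partition grid. All lengths are dimensionless user
units — designs are scale-free.

## Worked example

Two packaged specs reproduce a matched pair of 400 × 400 × 60 mm seawall
tiles: a **simple** tile (36 square pits, side and depth fixed at 32 mm,
ordered grid) and a **complex** tile (same pit count, side and depth drawn
uniformly from the 8–56 mm lattice in 8 mm steps, random placement, 8 mm
buffer). Because the lattice is symmetric about 32 mm, the complex tile's
*expected* surface area equals the simple tile's — complexity is decoupled
from area.

```
$ habtile generate src/habtile/examples/complex_tile.yaml --out-dir out
objects_placed 36
type_entropy 0 bits
combination_count 1296

$ habtile report out/design.json
type_entropy 0 bits (base 2)
size_levels pit footprint 7 (2.80735 bits)
size_levels pit depth 7 (2.80735 bits)
combination_count 1296 (36 components ^ 2 descriptors)
arrangement random
density 36
comparable_key arrangement=random;kinds=discrete-uniform
```

Reading: with a single pit type the type entropy is 0 bits; the complexity
lives in the size dimensions — 7 levels (2.81 bits) each for footprint and
depth — and in the random arrangement. The two varying attributes over 36
objects give 36² = 1296 combinations. The simple tile reports 1 level per
dimension and `comparable_key arrangement=ordered;kinds=fixed`: its entropy
must not be compared with the complex tile's (`assert_comparable` returns
`False`).

`generate` writes four files: `design.csv` (spreadsheet; one row per pit),
`design.dxf` (minimal R12 ASCII for CAD — boundary polyline on layer
`TILE`, one entity per pit on a per-type layer, depth in the thickness
attribute and mirrored on layer `DEPTH`), `design.svg` (drawing) and
`design.json` (lossless design record used by `report`, `edit` and
`validate`). `edit` applies move/resize/delete command files with strict
constraint revalidation; `validate` audits any design and exits non-zero on
violations. Exit codes: 0 success, 1 validation error, 2 infeasible
density.

The same functionality is available as a library:

```python
import habtile as h
spec = h.read_spec("src/habtile/examples/complex_tile.yaml")
design = h.generate_tile(spec)        # reproducible from (spec, seed)
h.validate_design(design)             # -> [] (no constraint violations)
h.surface_area(design)                # -> wetted area in mm²
h.complexity_report(design)           # -> entropy, levels, combinations
```

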