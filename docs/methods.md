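# Methods

## The model of complexity

`habtile` treats a substrate tile as a *static, informational* object: its
complexity is the information content of its configuration, with no
temporal or emergent component. The working metric is Shannon entropy.
For the vector of relative type abundances p the type entropy is
H(X) = −Σ pᵢ log₂ pᵢ. Log base 2 (bits) is used throughout and recorded in
every report (`entropy_base`); any other base is a constant factor. The
0·log 0 term is defined as 0 (the standard limit), so users can zero out a
type without triggering a validation error.

Entropy is deliberately *not* collapsed into a single compound score.
A report carries, separately: the type entropy; per-type, per-dimension
size-level counts and their log₂ (the entropy of uniform sampling over the
size lattice); the combination count `components ** descriptors`; the
arrangement rule; and the density. Like a Shannon–Wiener diversity index,
the entropy value alone under-determines the design and must travel with
these companions.

### Descriptors

The attribute list behind a combination count is not uniquely determined by
the five complexity variables, so it is a *user parameter*: report
functions accept an explicit `descriptors` override. The default is the
number of attributes able to take more than one value — type identity
(when k ≥ 2) plus each (type, dimension) pair with a non-degenerate
distribution. With this default, two objects of two types whose footprint
and depth each vary give 1 + 4 = 5 descriptors and 2⁵ = 32 combinations.
A fully homogeneous or empty tile has zero varying descriptors; its
combination count is defined as 1.

### Comparability

Entropy comparisons are only meaningful between tiles generated under the
same rules. Each report therefore carries a canonical `comparable_key`
encoding the arrangement mode, the set of size-distribution kinds, and
whether the design was hand-edited; `assert_comparable` simply compares
keys and callers are expected to gate on it. Continuous size ranges can be
*built* (`continuous-uniform`) but any request for their level count or
size entropy raises `UnsupportedComparisonError` instead of returning
infinity: a draw from a continuum has unbounded information content and a
comparison built on it would be meaningless rather than merely large.

## Generation pipeline

One `numpy` generator seeded from the spec drives the whole pipeline in a
fixed, documented order — abundances (drawn uniformly from the simplex via
a flat Dirichlet only when the spec leaves them unset), type assignment,
size sampling per type in spec order (footprint then depth), placement.
This ordering is a stability contract: identical (spec, seed) pairs yield
byte-identical serialised designs across refactors. Fixed distributions
consume no randomness.

*Type assignment* uses largest-remainder (Hamilton) apportionment of n·p:
exact, deterministic, each count within one unit of its quota; the rng
enters only to break ties among equal fractional remainders. *Size
sampling* is independent and uniform over the lattice
{min + j·increment}; the lattice bounds are validated to be an exact
multiple of the increment within a relative tolerance of 1e−9.

### Random placement

Random arrangement uses random sequential adsorption: centres proposed
uniformly over the tile, a proposal rejected if the footprint leaves the
tile or if the edge-to-edge gap to any placed object falls below the
buffer, with a cap of 10 000 proposals per object before an
`InfeasibleDensityError` (carrying attempt/rejection diagnostics) is
raised. RSA was chosen over soft-repulsion or optimisation approaches
because it gives *exact* buffer guarantees, which is what fabrication
needs, and is trivially auditable. Objects are inserted largest footprint
first — the standard RSA ordering, since large objects need the large voids
that only exist early; object ids keep the spec ordering, so the sort is
invisible in the output beyond improved feasibility.

Buffer semantics are edge-to-edge, not centre-to-centre. Gap formulas:
circles, centre distance minus the sum of radii; axis-aligned squares, the
Chebyshev-metric gap max(|dx|,|dy|) − (w₁+w₂)/2 (a conservative lower bound
on the true edge distance, so accepted layouts always satisfy the true
constraint); circle–square, point-to-rectangle distance minus the radius.
Footprints must lie fully inside the tile — a moulded tile cannot have pits
crossing the mould wall. Whether edge-clipped objects should ever be
allowed is a genuinely open design question; full containment is this
package's stated rule, not an inference about any predecessor.

### Ordered placement

Ordered arrangement is deterministic and consumes no randomness: r =
⌈√n⌉ rows, c = ⌈n/r⌉ columns, centres at the midpoints of an even partition
of the tile, filled row-major from the origin corner in spec type order.
For square n this is the regular lattice; for other n the last row is
partially filled. Containment and buffer are re-validated against the
realised sizes and violations raise the same infeasibility error. The
coordinate convention is origin at the lower-left corner, x rightwards, y
upwards, continuous real lengths in user units (the tile is scale-free; the
`units` label is export metadata only).

## Editing and the independent auditor

Advanced-mode edits (move / resize / delete, one object at a time) return a
new design; the input is never mutated. `validate_design` is the single
source of truth for physical validity and is implemented independently of
the placement engine — in particular square–square gaps use the exact
per-axis Euclidean separation rather than the placement engine's Chebyshev
bound, so the auditor can catch a placement bug rather than inherit it.
Constraint checks carry a 1e−9 absolute slack to absorb float rounding.

Strict mode (default) refuses any edit whose result fails the audit,
naming the offending object pairs; permissive mode attaches the violations
to the design as warnings and also allows off-lattice resizes. Either way
the design is marked `edited`, which voids entropy comparability — hand
placement breaks the sampling rules the comparison presumes. Deleting an
object decrements the spec's total count so the design stays
self-consistent.

## File formats

CSV output is plain comma-separated UTF-8 with a fixed header, decimal
points, and full `repr` precision — universally readable and diff-able; no
XLSX dependency. The CSV is intentionally minimal (one row per object), so
the CLI also persists a lossless JSON design record; `report`/`edit`/
`validate` consume the JSON, or a CSV paired with its spec file. DXF output
is the minimal R12 ASCII dialect, the most widely parseable: boundary as a
closed POLYLINE on layer `TILE`, circles as CIRCLE entities and squares as
closed POLYLINEs on a layer named after their type, pit depth in the
entity thickness (group 39) and mirrored as a TEXT note on layer `DEPTH`
because DXF has no standard "pit depth" attribute. Squares are
axis-aligned; no rotation. SVG output maps 1 user unit to 1 SVG unit with
the y axis flipped to SVG convention, and is a pure function of (design,
options). All writers are deterministic.

Domain types are frozen dataclasses with explicit validation rather than a
schema library, so every error can name the exact offending field path
(e.g. `object_types[0].footprint.increment`) as the I/O contracts require.

## Packaged study conditions

The two example specs encode a matched seawall-tile pair: 400 × 400 × 60 mm
tiles with 36 square pits. The simple tile fixes side and depth at 32 mm on
an ordered grid with an 8 mm buffer; the complex tile draws side and depth
uniformly from the 8–56 mm lattice in 8 mm steps (mean 32 mm) with random
placement and the same buffer. The pit count (36) and buffer (8 mm) are
this package's choices of a realistic fabrication layout at that tile size;
the 8–56 mm range, the 32 mm means, and the tile dimensions are the study
conditions the examples emulate. Because side and depth are independent and
their lattices are symmetric about the fixed values, a square pit's
expected wall area 4·E[w]·E[d] equals the simple pit's 4·32·32 mm², so the
complex tile's expected surface area equals the simple tile's; the test
suite verifies mean parity within 1% over 200 seeds (a 50-seed version runs
in the unit suite).

## What the generator does and does not emulate

Generated designs emulate the *specification* side of a field experiment:
geometry, abundances, lattices, spacing. They do not emulate fabrication
error, concrete shrinkage, surface texture, or any biological process —
passing tests show the designs are internally consistent and exportable,
not that any complexity level changes colonisation. Interactions among
components (e.g. clumping point processes) are out of scope by design: each
object is treated as an independent non-living feature, and the RSA
process is the only spatial structure imposed.

## Numerical choices and limitations

- Abundance vectors must sum to 1 within 1e−9 (absolute); entries must be
  non-negative. Lattice alignment uses 1e−9 relative tolerance.
- Problem sizes in the test and acceptance runs (500 audited designs of up
  to 12 objects, 200-seed parity, 50 round-trip designs) were chosen to
  exercise the contracts thoroughly while keeping the full suite in the
  seconds range on one CPU.
- RSA with a per-object attempt cap is not a maximal packer: feasible but
  very dense specs can still exhaust the cap, and the error deliberately
  reports that as infeasible *density* with diagnostics rather than
  retrying indefinitely. Densities well below the RSA jamming limit (as in
  the packaged examples) place reliably.
- Pits are vertical-walled right prisms/cylinders; surface area is planar
  area plus perimeter × depth. Sloped or undercut walls, and 3-D object
  shapes generally, are out of scope.
- The ordered grid rule for non-square n (partial last row) is this
  package's definition; other regular layouts (hex, centred) are not
  provided.
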