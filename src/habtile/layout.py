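"""Realise a :class:`~habtile.model.TileSpec` into a concrete tile design.

Generation is a fixed pipeline, all randomness drawn from one seeded
generator in a documented order so that identical (spec, seed) pairs yield
byte-identical designs:

1. abundances — drawn uniformly from the simplex if the spec leaves them
   unset, otherwise taken verbatim;
2. type assignment — largest-remainder apportionment of ``total_count``
   over the abundance vector (randomness only breaks remainder ties);
3. size sampling — per type in spec order, footprint then depth, uniform
   over the discrete lattice;
4. placement — random sequential adsorption (dart throwing) for
   ``arrangement = random``, a deterministic even-partition grid for
   ``arrangement = ordered``.

The buffer is an *edge-to-edge* minimum gap.  Footprints must lie fully
inside the tile: a fabricated mould cannot have pits crossing its wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import __version__
from .errors import InfeasibleDensityError, ValidationError
from .model import (
    CONTINUOUS,
    DISCRETE,
    FIXED,
    PlacedObject,
    SizeDistribution,
    TileDesign,
    TileSpec,
    _validate_probability_vector,
)

__all__ = [
    "PlacementDiagnostics",
    "SizedObject",
    "assign_types",
    "randomize_abundances",
    "sample_sizes",
    "place_random",
    "place_ordered",
    "generate_tile",
]

#: Default cap on placement proposals per object before giving up.
DEFAULT_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class PlacementDiagnostics:
    """Bookkeeping from a placement run, attached to infeasibility errors."""

    attempts_used: int
    rejected_overlap: int
    rejected_bounds: int
    achieved_count: int


class SizedObject(NamedTuple):
    """An object that has a type and realised sizes but no position yet."""

    type_id: str
    shape: str
    footprint_size: float
    depth: float


# ---------------------------------------------------------------------------
# apportionment and sampling
# ---------------------------------------------------------------------------

def assign_types(n: int, p: Sequence[float], rng: np.random.Generator) -> list[int]:
    """Apportion ``n`` objects over types with probabilities ``p``.

    Largest-remainder (Hamilton) apportionment: each type gets
    ``floor(n * p_i)``, then leftover units go to the largest fractional
    remainders.  Deterministic except that ties among equal remainders are
    broken by a random permutation.  Counts always sum to exactly ``n`` and
    each is within one unit of ``n * p_i``.
    """
    arr = _validate_probability_vector(p, what="p")
    if n < 0:
        raise ValidationError(f"n must be non-negative, got {n!r}")
    quota = n * arr
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = int(n - base.sum())
    if short > 0:
        # rng enters only when distinct types share a fractional remainder
        if len(np.unique(remainder)) < len(remainder):
            tiebreak = rng.permutation(len(remainder))
        else:
            tiebreak = np.arange(len(remainder))
        order = sorted(range(len(remainder)), key=lambda i: (-remainder[i], tiebreak[i]))
        for i in order[:short]:
            base[i] += 1
    return [int(c) for c in base]


def randomize_abundances(k: int, rng: np.random.Generator) -> tuple[float, ...]:
    """Draw an abundance vector uniformly from the (k-1)-simplex."""
    if not isinstance(k, int) or k < 1:
        raise ValidationError(f"k must be an integer >= 1, got {k!r}")
    draw = rng.dirichlet(np.ones(k))
    draw = draw / draw.sum()  # crush float drift so the sum-to-one check holds
    return tuple(float(x) for x in draw)


def sample_sizes(dist: SizeDistribution, count: int,
                 rng: np.random.Generator) -> list[float]:
    """Sample ``count`` lengths from a size distribution.

    Discrete-uniform values land exactly on the lattice
    ``{minimum + j * increment}``, each level equally likely and draws
    independent.  Fixed distributions return the constant without touching
    the rng.  Continuous-uniform draws reals over [minimum, maximum]; such
    designs are buildable but excluded from complexity comparison.
    """
    if count < 0:
        raise ValidationError(f"count must be non-negative, got {count!r}")
    if dist.kind == FIXED:
        return [dist.minimum] * count
    if dist.kind == DISCRETE:
        n_levels = int(round((dist.maximum - dist.minimum) / dist.increment)) + 1
        idx = rng.integers(0, n_levels, size=count)
        return [dist.minimum + int(j) * dist.increment for j in idx]
    assert dist.kind == CONTINUOUS
    return [float(v) for v in rng.uniform(dist.minimum, dist.maximum, size=count)]


# ---------------------------------------------------------------------------
# pairwise gap geometry (placement-side; the audit module re-derives its own)
# ---------------------------------------------------------------------------

def _placement_gap(shape_a: str, xa: float, ya: float, wa: float,
                   shape_b: str, xb: float, yb: float, wb: float) -> float:
    """Edge-to-edge gap used by the placement accept/reject test.

    circle-circle: centre distance minus the radii.  square-square:
    Chebyshev-metric gap (a conservative lower bound on the true
    edge-to-edge distance for axis-aligned squares).  circle-square: point
    to rectangle distance minus the radius.  Negative means overlap.
    """
    dx, dy = xb - xa, yb - ya
    if shape_a == "circle" and shape_b == "circle":
        return math.hypot(dx, dy) - (wa + wb) / 2.0
    if shape_a == "square" and shape_b == "square":
        return max(abs(dx), abs(dy)) - (wa + wb) / 2.0
    # mixed: make a the circle
    if shape_a == "square":
        shape_a, xa, ya, wa, shape_b, xb, yb, wb = shape_b, xb, yb, wb, shape_a, xa, ya, wa
        dx, dy = -dx, -dy
    gx = max(abs(dx) - wb / 2.0, 0.0)
    gy = max(abs(dy) - wb / 2.0, 0.0)
    return math.hypot(gx, gy) - wa / 2.0


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_random(spec: TileSpec, sized_objects: Sequence[SizedObject],
                 rng: np.random.Generator,
                 max_attempts: int = DEFAULT_MAX_ATTEMPTS) -> TileDesign:
    """Place objects by random sequential adsorption (dart throwing).

    Centres are proposed uniformly over the tile; a proposal is rejected if
    the footprint leaves the tile or if its edge-to-edge gap to any already
    placed object falls below the buffer.  Objects are inserted largest
    footprint first (a deterministic, stable sort) — the standard sequential-
    adsorption ordering, since large objects need the large voids that only
    exist early.  Object ids still follow the original (spec-order) listing.
    Each object gets at most ``max_attempts`` proposals; exhausting them
    raises :class:`InfeasibleDensityError` carrying
    :class:`PlacementDiagnostics`.
    """
    W, L = spec.tile_width, spec.tile_length
    placed: list[PlacedObject] = []
    placed_shapes: list[str] = []
    attempts = rejected_overlap = rejected_bounds = 0
    order = sorted(range(len(sized_objects)),
                   key=lambda i: -sized_objects[i].footprint_size)
    for i in order:
        so = sized_objects[i]
        half = so.footprint_size / 2.0
        ok = False
        for _ in range(max_attempts):
            attempts += 1
            x = float(rng.uniform(0.0, W))
            y = float(rng.uniform(0.0, L))
            if x - half < 0 or x + half > W or y - half < 0 or y + half > L:
                rejected_bounds += 1
                continue
            clash = False
            for prev, prev_shape in zip(placed, placed_shapes):
                if _placement_gap(so.shape, x, y, so.footprint_size,
                                  prev_shape, prev.centre_x, prev.centre_y,
                                  prev.footprint_size) < spec.buffer:
                    clash = True
                    break
            if clash:
                rejected_overlap += 1
                continue
            placed.append(PlacedObject(i, so.type_id, x, y, so.footprint_size, so.depth))
            placed_shapes.append(so.shape)
            ok = True
            break
        if not ok:
            diag = PlacementDiagnostics(attempts, rejected_overlap,
                                        rejected_bounds, len(placed))
            raise InfeasibleDensityError(
                f"could not place object {i} ({so.type_id}, footprint "
                f"{so.footprint_size}) within {max_attempts} attempts; "
                f"density/buffer combination is infeasible", diag)
    placed.sort(key=lambda o: o.object_id)
    return TileDesign(spec=spec, objects=tuple(placed), seed=spec.seed,
                      generator_version=__version__)


def place_ordered(spec: TileSpec, sized_objects: Sequence[SizedObject]) -> TileDesign:
    """Lay objects on a deterministic even-partition grid (no randomness).

    With n objects the grid has ``r = ceil(sqrt(n))`` rows and
    ``c = ceil(n / r)`` columns; centres sit at the midpoints of an even
    partition of the tile and fill row-major from the origin corner in spec
    type order.  Containment and buffer constraints are re-validated against
    the realised sizes; a grid too tight for them raises
    :class:`InfeasibleDensityError`.
    """
    n = len(sized_objects)
    W, L = spec.tile_width, spec.tile_length
    placed: list[PlacedObject] = []
    if n > 0:
        r = math.isqrt(n)
        rows = r if r * r == n else r + 1  # ceil(sqrt(n)) in exact arithmetic
        cols = -(-n // rows)  # ceil(n / rows)
        cell_w, cell_h = W / cols, L / rows
        for i, so in enumerate(sized_objects):
            row, col = divmod(i, cols)
            x = (col + 0.5) * cell_w
            y = (row + 0.5) * cell_h
            half = so.footprint_size / 2.0
            if x - half < -1e-12 or x + half > W + 1e-12 \
                    or y - half < -1e-12 or y + half > L + 1e-12:
                raise InfeasibleDensityError(
                    f"ordered grid cell ({cell_w:g} x {cell_h:g}) too small for "
                    f"object {i} footprint {so.footprint_size}",
                    PlacementDiagnostics(0, 0, n - len(placed), len(placed)))
            placed.append(PlacedObject(i, so.type_id, x, y, so.footprint_size, so.depth))
        for a in range(n):
            for b in range(a + 1, n):
                oa, ob = placed[a], placed[b]
                gap = _placement_gap(sized_objects[a].shape, oa.centre_x, oa.centre_y,
                                     oa.footprint_size, sized_objects[b].shape,
                                     ob.centre_x, ob.centre_y, ob.footprint_size)
                if gap < spec.buffer:
                    raise InfeasibleDensityError(
                        f"ordered grid leaves gap {gap:g} between objects {a} and "
                        f"{b}, below buffer {spec.buffer:g}",
                        PlacementDiagnostics(0, 1, 0, 0))
    return TileDesign(spec=spec, objects=tuple(placed), seed=spec.seed,
                      generator_version=__version__)


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate_tile(spec: TileSpec,
                  max_attempts: int = DEFAULT_MAX_ATTEMPTS) -> TileDesign:
    """Generate a complete tile design from a spec, reproducibly.

    One seeded generator drives the whole pipeline (abundances, type
    assignment, sizes, placement, in that order), so the same (spec, seed)
    always returns an identical design.  The resolved abundance vector is
    frozen into the returned design's spec so reports on randomised-
    abundance tiles use the abundances actually drawn.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.abundances is None:
        p = randomize_abundances(spec.n_types, rng)
        spec = replace(spec, abundances=p)
    else:
        p = spec.abundances
    counts = assign_types(spec.total_count, p, rng)
    sized: list[SizedObject] = []
    for t, c in zip(spec.object_types, counts):
        footprints = sample_sizes(t.footprint, c, rng)
        depths = sample_sizes(t.depth, c, rng)
        sized.extend(SizedObject(t.type_id, t.shape, f, d)
                     for f, d in zip(footprints, depths))
    if spec.arrangement == "random":
        return place_random(spec, sized, rng, max_attempts=max_attempts)
    return place_ordered(spec, sized)
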