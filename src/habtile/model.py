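"""Domain model and informational-complexity metrics for substrate tiles.

A tile is a flat rectangular substrate (e.g. a concrete seawall tile) whose
topography is built from discrete surface objects — vertical-walled pits,
circular or square in plan.  Informational complexity of such a static
configuration is controlled through five variables:

1. the number of object *types* (colour classes),
2. the *relative abundance* of each type,
3. the *density* (total object count),
4. the *variability and range* of object dimensions, and
5. the *spatial arrangement* (random vs ordered).

The headline metric is Shannon entropy over the type-abundance vector,

    H(X) = -sum_i p_i * log2(p_i)    [bits],

reported alongside per-dimension size-level counts (and their log2, the
entropy of uniform sampling over the discrete size lattice) and the
components**descriptors combination count.  Entropy values are only
meaningful between tiles generated under the same rules — same arrangement
mode, same distribution kinds — which :func:`assert_comparable` enforces via
a canonical ``comparable_key``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from numbers import Integral
from typing import Mapping, Sequence

import numpy as np

from .errors import UnsupportedComparisonError, ValidationError

__all__ = [
    "ABUNDANCE_TOL",
    "LATTICE_RTOL",
    "SizeDistribution",
    "ObjectTypeSpec",
    "TileSpec",
    "PlacedObject",
    "TileDesign",
    "ComplexityReport",
    "shannon_entropy",
    "combination_count",
    "size_level_count",
    "size_levels",
    "surface_area",
    "varying_descriptor_count",
    "complexity_report",
    "assert_comparable",
]

#: Absolute tolerance on "abundances sum to one".
ABUNDANCE_TOL = 1e-9
#: Relative tolerance on "(max - min) is an integer multiple of increment".
LATTICE_RTOL = 1e-9

FIXED = "fixed"
DISCRETE = "discrete-uniform"
CONTINUOUS = "continuous-uniform"

_SHAPES = ("circle", "square")
_ARRANGEMENTS = ("random", "ordered")


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeDistribution:
    """Distribution of one object dimension (footprint or depth).

    ``fixed`` is a point mass, ``discrete-uniform`` samples uniformly from
    the lattice ``{minimum + j * increment}``, and ``continuous-uniform``
    samples uniformly from the real interval.  Continuous ranges can be
    realised but are excluded from level/entropy accounting: the information
    content of a draw from a continuum is unbounded, so complexity
    comparisons built on it are rejected rather than reported as infinite.

    Lengths are dimensionless user units; the tile spec carries a free-text
    units label for export metadata only.
    """

    kind: str
    minimum: float
    maximum: float
    increment: float | None = None

    def __post_init__(self):
        if self.kind not in (FIXED, DISCRETE, CONTINUOUS):
            raise ValidationError(f"unknown size-distribution kind {self.kind!r}")
        if not (self.minimum > 0 and math.isfinite(self.minimum)):
            raise ValidationError(f"minimum must be a positive length, got {self.minimum!r}")
        if not (self.maximum > 0 and math.isfinite(self.maximum)):
            raise ValidationError(f"maximum must be a positive length, got {self.maximum!r}")
        if self.minimum > self.maximum:
            raise ValidationError(
                f"minimum {self.minimum!r} exceeds maximum {self.maximum!r}")
        if self.kind == FIXED:
            if self.minimum != self.maximum:
                raise ValidationError(
                    f"fixed distribution needs minimum == maximum, got "
                    f"{self.minimum!r} != {self.maximum!r}")
            if self.increment is not None:
                raise ValidationError("fixed distribution takes no increment")
        elif self.kind == DISCRETE:
            if self.increment is None or not self.increment > 0:
                raise ValidationError(
                    f"discrete-uniform distribution needs increment > 0, got "
                    f"{self.increment!r}")
            span = self.maximum - self.minimum
            steps = span / self.increment
            if abs(steps - round(steps)) > LATTICE_RTOL * max(1.0, abs(steps)):
                raise ValidationError(
                    f"(maximum - minimum) = {span!r} is not an integer multiple "
                    f"of increment {self.increment!r}")
        else:  # continuous
            if self.increment is not None:
                raise ValidationError("continuous distribution takes no increment")
            if self.minimum == self.maximum:
                raise ValidationError(
                    "continuous distribution needs minimum < maximum")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def fixed(cls, value: float) -> "SizeDistribution":
        return cls(FIXED, value, value)

    @classmethod
    def discrete(cls, minimum: float, maximum: float, increment: float) -> "SizeDistribution":
        return cls(DISCRETE, minimum, maximum, increment)

    @classmethod
    def continuous(cls, minimum: float, maximum: float) -> "SizeDistribution":
        return cls(CONTINUOUS, minimum, maximum)

    @property
    def is_varying(self) -> bool:
        """True if more than one outcome is possible."""
        return self.kind != FIXED


@dataclass(frozen=True)
class ObjectTypeSpec:
    """One object type: a colour class with footprint and depth distributions.

    ``footprint`` is the diameter of a circular pit or the side of a square
    pit; ``depth`` is the recess depth below the tile face.
    """

    type_id: str
    colour: str
    footprint: SizeDistribution
    depth: SizeDistribution
    shape: str = "circle"

    def __post_init__(self):
        if not self.type_id:
            raise ValidationError("type_id must be a non-empty string")
        if self.shape not in _SHAPES:
            raise ValidationError(
                f"object type {self.type_id!r}: shape must be one of {_SHAPES}, "
                f"got {self.shape!r}")


@dataclass(frozen=True)
class TileSpec:
    """Full specification of a tile: geometry plus the five complexity variables.

    ``abundances`` is the probability vector over ``object_types``; pass
    ``None`` to have it redrawn uniformly from the simplex at each
    generation.  ``buffer`` is the minimum *edge-to-edge* gap enforced
    between any two placed objects.  ``tile_thickness`` is fabrication
    metadata only and takes no part in layout or metrics.
    """

    tile_width: float
    tile_length: float
    object_types: tuple[ObjectTypeSpec, ...]
    total_count: int
    arrangement: str = "random"
    abundances: tuple[float, ...] | None = None
    buffer: float = 0.0
    seed: int = 0
    tile_thickness: float = 1.0
    units: str = "units"

    def __post_init__(self):
        object.__setattr__(self, "object_types", tuple(self.object_types))
        if self.abundances is not None:
            object.__setattr__(self, "abundances", tuple(float(p) for p in self.abundances))
        for name in ("tile_width", "tile_length", "tile_thickness"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{name} must be a positive length, got {v!r}")
        if not self.object_types:
            raise ValidationError("object_types must contain at least one type")
        ids = [t.type_id for t in self.object_types]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate type_id(s): {dup}")
        if self.abundances is not None:
            if len(self.abundances) != len(self.object_types):
                raise ValidationError(
                    f"abundances has length {len(self.abundances)} but there are "
                    f"{len(self.object_types)} object types")
            _validate_probability_vector(self.abundances, what="abundances")
        if not isinstance(self.total_count, Integral) or self.total_count < 0:
            raise ValidationError(
                f"total_count must be a non-negative integer, got {self.total_count!r}")
        if self.arrangement not in _ARRANGEMENTS:
            raise ValidationError(
                f"arrangement must be one of {_ARRANGEMENTS}, got {self.arrangement!r}")
        if self.buffer < 0:
            raise ValidationError(f"buffer must be non-negative, got {self.buffer!r}")
        if not isinstance(self.seed, Integral) or self.seed < 0:
            raise ValidationError(f"seed must be a non-negative integer, got {self.seed!r}")

    @property
    def n_types(self) -> int:
        return len(self.object_types)

    def type_by_id(self, type_id: str) -> ObjectTypeSpec:
        for t in self.object_types:
            if t.type_id == type_id:
                return t
        raise ValidationError(f"unknown type_id {type_id!r}")


# ---------------------------------------------------------------------------
# realised-design types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacedObject:
    """One realised object: a pit at (centre_x, centre_y) with realised sizes."""

    object_id: int
    type_id: str
    centre_x: float
    centre_y: float
    footprint_size: float
    depth: float

    def __post_init__(self):
        if self.footprint_size <= 0:
            raise ValidationError(
                f"object {self.object_id}: footprint_size must be positive")
        if self.depth <= 0:
            raise ValidationError(f"object {self.object_id}: depth must be positive")


@dataclass(frozen=True)
class TileDesign:
    """A tile spec together with its realised objects.

    ``edited`` flags designs touched by manual (advanced-mode) edits; such
    designs may hold off-lattice sizes and their ``comparable_key`` is
    marked so entropy comparisons against generated designs are refused.
    """

    spec: TileSpec
    objects: tuple[PlacedObject, ...]
    seed: int | None = None
    generator_version: str = ""
    edited: bool = False
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "objects", tuple(self.objects))
        object.__setattr__(self, "warnings", tuple(self.warnings))
        ids = [o.object_id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValidationError("object_id values must be unique within a design")
        for o in self.objects:
            self.spec.type_by_id(o.type_id)  # raises on dangling reference

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def object_by_id(self, object_id: int) -> PlacedObject:
        for o in self.objects:
            if o.object_id == object_id:
                return o
        from .errors import ObjectNotFoundError
        raise ObjectNotFoundError(f"no object with id {object_id} in design")

    def shape_of(self, obj: PlacedObject) -> str:
        return self.spec.type_by_id(obj.type_id).shape


@dataclass(frozen=True)
class ComplexityReport:
    """All informational-complexity metrics of one design.

    ``size_level_counts`` / ``size_entropy`` map type_id -> dimension name
    ("footprint", "depth") -> value.  ``comparable_key`` canonically encodes
    the generation rules (arrangement mode + distribution kinds + edited
    flag); entropy comparisons are legitimate only between reports whose
    keys match.
    """

    type_entropy: float
    entropy_base: int
    size_level_counts: Mapping[str, Mapping[str, int]]
    size_entropy: Mapping[str, Mapping[str, float]]
    combination_count: int
    descriptor_count: int
    arrangement_rule: str
    density: int
    comparable_key: str


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _validate_probability_vector(p: Sequence[float], what: str = "p") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{what} must be a non-empty 1-d probability vector")
    neg = np.nonzero(arr < 0)[0]
    if neg.size:
        i = int(neg[0])
        raise ValidationError(f"{what}[{i}] = {arr[i]!r} is negative")
    total = float(arr.sum())
    if abs(total - 1.0) > ABUNDANCE_TOL:
        raise ValidationError(f"{what} sums to {total!r}, not 1 (tolerance {ABUNDANCE_TOL})")
    return arr


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy H(X) = -sum p_i log2 p_i of a probability vector, in bits.

    Zero-probability entries contribute nothing (the 0*log 0 := 0 limit), so
    a type can be zeroed out without error.  The result lies in
    [0, log2 k] and attains the upper bound iff all positive entries are
    equal and none is zero.
    """
    arr = _validate_probability_vector(p)
    pos = arr[arr > 0]
    return float(-(pos * np.log2(pos)).sum()) + 0.0  # +0.0 normalises -0.0


def combination_count(components: int, descriptors: int) -> int:
    """Number of distinguishable configurations: components ** descriptors.

    ``components`` is the object count (density); ``descriptors`` the number
    of independently varying attributes (heterogeneity).  Heterogeneity is
    the higher-order factor: 2 components with 5 descriptors admit 2**5 = 32
    combinations, while 5 components with 2 descriptors admit only 5**2 = 25.
    Exact integer arithmetic.
    """
    for name, v in (("components", components), ("descriptors", descriptors)):
        if not isinstance(v, Integral) or isinstance(v, bool) or v < 1:
            raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")
    return int(components) ** int(descriptors)


def size_levels(dist: SizeDistribution) -> list[float]:
    """The discrete lattice of realisable values, smallest first."""
    if dist.kind == FIXED:
        return [dist.minimum]
    if dist.kind == DISCRETE:
        n = size_level_count(dist)
        return [dist.minimum + j * dist.increment for j in range(n)]
    raise UnsupportedComparisonError(
        "continuous size range has no discrete levels; complexity comparison "
        "over continuous ranges is unsupported")


def size_level_count(dist: SizeDistribution) -> int:
    """Number of distinct values a dimension can take.

    Fixed -> 1.  Discrete-uniform over [min, max] with step ``increment`` ->
    (max - min)/increment + 1.  Smaller increments over the same range give
    more levels, hence more complexity.  Continuous ranges raise
    :class:`UnsupportedComparisonError`: every draw from a continuum is
    vanishingly improbable, so level counting (and any entropy comparison
    built on it) is undefined.
    """
    if dist.kind == FIXED:
        return 1
    if dist.kind == DISCRETE:
        return int(round((dist.maximum - dist.minimum) / dist.increment)) + 1
    raise UnsupportedComparisonError(
        "continuous size range admits no level count; comparisons between "
        "tiles sampled from continuous ranges are unsupported")


def surface_area(design: TileDesign) -> float:
    """Total wetted surface area of the tile face, in user units squared.

    Pits are vertical-walled recesses: the pit floor replaces the opening it
    removes from the face (net planar change zero), so each pit adds only
    its wall area — ``4 * w * d`` for a square pit of side w and depth d,
    ``pi * w * d`` for a circular pit of diameter w.
    """
    area = design.spec.tile_width * design.spec.tile_length
    for obj in design.objects:
        if design.shape_of(obj) == "square":
            area += 4.0 * obj.footprint_size * obj.depth
        else:
            area += math.pi * obj.footprint_size * obj.depth
    return area


def varying_descriptor_count(spec: TileSpec) -> int:
    """Default descriptor count: attributes able to take more than one value.

    Counts type identity as one attribute when there are >= 2 types, plus
    each (type, dimension) pair whose distribution is non-degenerate.  The
    attribute list behind a combination count is ultimately the user's
    modelling choice; report functions accept an explicit override.
    """
    count = 1 if spec.n_types > 1 else 0
    for t in spec.object_types:
        count += int(t.footprint.is_varying)
        count += int(t.depth.is_varying)
    return count


def _comparable_key(spec: TileSpec, edited: bool) -> str:
    kinds = sorted({d.kind for t in spec.object_types for d in (t.footprint, t.depth)})
    key = f"arrangement={spec.arrangement};kinds={','.join(kinds)}"
    if edited:
        key += ";edited"
    return key


def complexity_report(design: TileDesign, descriptors: int | None = None) -> ComplexityReport:
    """Assemble every complexity metric of a design into one report.

    The type entropy uses the spec's abundance vector when one is declared;
    for randomised-abundance specs it falls back to the realised per-type
    proportions.  ``descriptors`` overrides the default varying-attribute
    count used for the combination count (see
    :func:`varying_descriptor_count`).
    """
    spec = design.spec
    if spec.abundances is not None:
        p = list(spec.abundances)
    elif design.n_objects > 0:
        counts = {t.type_id: 0 for t in spec.object_types}
        for o in design.objects:
            counts[o.type_id] += 1
        p = [counts[t.type_id] / design.n_objects for t in spec.object_types]
    else:
        p = [1.0] + [0.0] * (spec.n_types - 1)
    h_type = shannon_entropy(p)

    level_counts: dict[str, dict[str, int]] = {}
    size_h: dict[str, dict[str, float]] = {}
    for t in spec.object_types:
        level_counts[t.type_id] = {
            "footprint": size_level_count(t.footprint),
            "depth": size_level_count(t.depth),
        }
        size_h[t.type_id] = {
            dim: math.log2(c) for dim, c in level_counts[t.type_id].items()
        }

    d = varying_descriptor_count(spec) if descriptors is None else int(descriptors)
    if d < 0:
        raise ValidationError(f"descriptors must be >= 0, got {descriptors!r}")
    n = design.n_objects
    combos = combination_count(n, d) if (n >= 1 and d >= 1) else 1

    return ComplexityReport(
        type_entropy=h_type,
        entropy_base=2,
        size_level_counts=level_counts,
        size_entropy=size_h,
        combination_count=combos,
        descriptor_count=d,
        arrangement_rule=spec.arrangement,
        density=n,
        comparable_key=_comparable_key(spec, design.edited),
    )


def assert_comparable(a: ComplexityReport, b: ComplexityReport) -> bool:
    """True iff two reports were produced under identical rules.

    Entropy is only meaningful between tiles generated with the same rules:
    the same arrangement mode and the same distribution kinds (and neither
    hand-edited).  Callers must gate any entropy comparison on this; the
    function returns False rather than raising so it can be used as a guard.
    """
    return a.comparable_key == b.comparable_key


def mark_edited(design: TileDesign) -> TileDesign:
    """Return a copy of the design flagged as manually edited."""
    return replace(design, edited=True)
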