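"""Advanced mode: per-object editing of a realised design.

Users can move an object, resize its footprint or depth, or delete it.
Edits are checked against the same physical constraints the generator
enforces — footprints inside the tile, pairwise edge-to-edge gaps at least
the buffer — by :func:`validate_design`, an auditor written independently
of the placement engine so it can serve as the single source of truth.

Any manual edit marks the design as ``edited``: hand-placed or resized
objects no longer follow the sampling rules, so entropy comparisons against
generated tiles are refused (the report's comparable_key carries the mark).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConstraintError, ValidationError
from .model import PlacedObject, TileDesign

__all__ = ["EditCommand", "Violation", "apply_edit", "validate_design"]

#: Slack on constraint checks, absorbing float rounding in gap arithmetic.
GEOM_TOL = 1e-9

_KINDS = ("move", "resize", "delete")


@dataclass(frozen=True)
class EditCommand:
    """One edit: move / resize / delete a single object by id."""

    kind: str
    object_id: int
    new_centre: tuple[float, float] | None = None
    new_footprint_size: float | None = None
    new_depth: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"edit kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "move" and self.new_centre is None:
            raise ValidationError("move edit requires new_centre")
        if self.kind == "resize" and self.new_footprint_size is None \
                and self.new_depth is None:
            raise ValidationError("resize edit requires a new footprint size or depth")


@dataclass(frozen=True)
class Violation:
    """One constraint breach: which objects, the measured gap, the required gap.

    ``kind`` is "containment" (measured = worst signed margin to a tile
    edge, required 0) or "overlap" (measured = signed edge-to-edge gap,
    required = buffer).  Negative measured gaps mean interpenetration.
    """

    kind: str
    object_ids: tuple[int, ...]
    measured_gap: float
    required_gap: float

    def __str__(self):
        ids = ",".join(str(i) for i in self.object_ids)
        return (f"{self.kind} violation (objects {ids}): gap {self.measured_gap:.6g} "
                f"< required {self.required_gap:.6g}")


# ---------------------------------------------------------------------------
# independent constraint auditor
# ---------------------------------------------------------------------------
# Deliberately re-derived from the tile geometry rather than shared with the
# placement engine: square-square gaps use the per-axis Euclidean separation
# (exact for axis-aligned squares), not the placement engine's Chebyshev test.

def _signed_gap(shape_a, xa, ya, wa, shape_b, xb, yb, wb) -> float:
    dx, dy = abs(xb - xa), abs(yb - ya)
    if shape_a == "circle" and shape_b == "circle":
        return math.hypot(dx, dy) - (wa + wb) / 2.0
    if shape_a == "square" and shape_b == "square":
        ax = dx - (wa + wb) / 2.0
        ay = dy - (wa + wb) / 2.0
        if ax > 0.0 or ay > 0.0:
            return math.hypot(max(ax, 0.0), max(ay, 0.0))
        return max(ax, ay)  # penetration depth, negative
    if shape_a == "square":  # normalise to (circle, square)
        shape_a, wa, shape_b, wb = shape_b, wb, shape_a, wa
    gx = dx - wb / 2.0
    gy = dy - wb / 2.0
    if gx > 0.0 or gy > 0.0:
        return math.hypot(max(gx, 0.0), max(gy, 0.0)) - wa / 2.0
    return max(gx, gy) - wa / 2.0


def validate_design(design: TileDesign) -> list[Violation]:
    """Audit a design against containment and buffer constraints.

    Returns every breach as a :class:`Violation`; an empty list means the
    design is physically valid.  Every design emitted by the generator and
    every strict-accepted edit must audit clean.
    """
    spec = design.spec
    W, L = spec.tile_width, spec.tile_length
    out: list[Violation] = []
    shapes = {o.object_id: design.shape_of(o) for o in design.objects}
    for o in design.objects:
        half = o.footprint_size / 2.0
        margin = min(o.centre_x - half, W - o.centre_x - half,
                     o.centre_y - half, L - o.centre_y - half)
        if margin < -GEOM_TOL:
            out.append(Violation("containment", (o.object_id,), margin, 0.0))
    objs = design.objects
    for i in range(len(objs)):
        for j in range(i + 1, len(objs)):
            a, b = objs[i], objs[j]
            gap = _signed_gap(shapes[a.object_id], a.centre_x, a.centre_y,
                              a.footprint_size, shapes[b.object_id],
                              b.centre_x, b.centre_y, b.footprint_size)
            if gap < spec.buffer - GEOM_TOL:
                out.append(Violation("overlap", (a.object_id, b.object_id),
                                     gap, spec.buffer))
    return out


# ---------------------------------------------------------------------------
# edit application
# ---------------------------------------------------------------------------

def apply_edit(design: TileDesign, cmd: EditCommand,
               strict: bool = True) -> TileDesign:
    """Apply one edit and return a new design; the original is untouched.

    In strict mode (default) the edited design must audit clean or the edit
    is refused with a :class:`ConstraintError` naming the offending object
    pairs — the safe default for fabrication.  In permissive mode breaches
    are attached to the returned design as warnings instead, and resized
    dimensions may leave the discrete lattice.  Either way the result is
    marked ``edited``, which voids complexity comparability.
    """
    target = design.object_by_id(cmd.object_id)  # ObjectNotFoundError if absent

    if cmd.kind == "delete":
        remaining = tuple(o for o in design.objects if o.object_id != cmd.object_id)
        new_spec = replace(design.spec, total_count=len(remaining))
        return replace(design, spec=new_spec, objects=remaining, edited=True,
                       warnings=())

    changes: dict = {}
    if cmd.kind == "move":
        changes["centre_x"], changes["centre_y"] = cmd.new_centre
    else:  # resize
        if cmd.new_footprint_size is not None:
            if cmd.new_footprint_size <= 0:
                raise ValidationError(
                    f"new footprint size must be positive, got {cmd.new_footprint_size!r}")
            changes["footprint_size"] = cmd.new_footprint_size
        if cmd.new_depth is not None:
            if cmd.new_depth <= 0:
                raise ValidationError(f"new depth must be positive, got {cmd.new_depth!r}")
            changes["depth"] = cmd.new_depth

    new_obj: PlacedObject = replace(target, **changes)
    new_objects = tuple(new_obj if o.object_id == cmd.object_id else o
                        for o in design.objects)
    candidate = replace(design, objects=new_objects, edited=True, warnings=())

    violations = validate_design(candidate)
    if violations:
        if strict:
            raise ConstraintError(
                "edit refused: " + "; ".join(str(v) for v in violations),
                violations)
        candidate = replace(candidate, warnings=tuple(str(v) for v in violations))
    return candidate
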