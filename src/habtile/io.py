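"""Readers, writers and rendering.

Formats:

* **spec YAML** — the structured tile-specification file (schema below);
* **design CSV** — one row per placed object, plain comma-separated UTF-8
  with a header, decimal points, full ``repr`` precision: readable by any
  spreadsheet and diff-able;
* **design JSON** — lossless persistence of a whole design (spec + objects
  + provenance), the format the CLI round-trips through;
* **DXF** — minimal R12 ASCII for CAD import: tile boundary as a closed
  polyline on layer ``TILE``, circles as CIRCLE entities and squares as
  closed polylines on a per-type layer, pit depth in the entity thickness
  (group 39) and mirrored as a TEXT annotation on layer ``DEPTH`` (DXF has
  no standard notion of pit depth);
* **SVG 1.1** — a deterministic drawing, 1 user unit = 1 SVG unit, objects
  filled by type colour.

Spec YAML schema (flat keys; lengths in user units)::

    tile: {width: 400, length: 400, thickness: 60}
    units: mm
    object_types:
      - id: pit
        colour: "#336699"
        shape: square                    # circle | square
        footprint: {kind: discrete-uniform, minimum: 8, maximum: 56, increment: 8}
        depth: {kind: fixed, value: 32}  # or minimum/maximum/increment
    abundances: [1.0]                    # or the string "random"
    total_count: 36
    arrangement: ordered                 # random | ordered
    buffer: 8
    seed: 7
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError
from .model import (
    ComplexityReport,
    ObjectTypeSpec,
    PlacedObject,
    SizeDistribution,
    TileDesign,
    TileSpec,
    complexity_report,
)

__all__ = [
    "ExportOptions",
    "read_spec", "write_spec",
    "write_design_csv", "read_design_csv",
    "write_design_json", "read_design_json",
    "write_design_dxf", "render_svg",
    "export_design",
]

CSV_HEADER = ["object_id", "type_id", "shape", "centre_x", "centre_y",
              "footprint_size", "depth"]

_FORMATS = ("csv", "dxf", "svg")


@dataclass(frozen=True)
class ExportOptions:
    formats: tuple[str, ...] = ("csv", "dxf", "svg")
    units_label: str = ""
    colour_map: dict[str, str] | None = None
    include_report: bool = False

    def __post_init__(self):
        object.__setattr__(self, "formats", tuple(self.formats))
        if not self.formats:
            raise ValidationError("at least one export format must be selected")
        bad = [f for f in self.formats if f not in _FORMATS]
        if bad:
            raise ValidationError(f"unknown export format(s) {bad}; choose from {_FORMATS}")


def _num(x: float) -> str:
    """Full-precision, locale-free decimal representation."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# spec YAML
# ---------------------------------------------------------------------------

def _dist_from_dict(d: dict, path: str) -> SizeDistribution:
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: expected a mapping, got {type(d).__name__}")
    kind = d.get("kind", "fixed")
    try:
        if kind == "fixed":
            if "value" in d:
                return SizeDistribution.fixed(float(d["value"]))
            return SizeDistribution.fixed(float(d["minimum"]))
        if kind == "discrete-uniform":
            return SizeDistribution.discrete(float(d["minimum"]), float(d["maximum"]),
                                             float(d["increment"]))
        if kind == "continuous-uniform":
            return SizeDistribution.continuous(float(d["minimum"]), float(d["maximum"]))
    except KeyError as e:
        raise ValidationError(f"{path}: missing field {e.args[0]!r} for kind {kind!r}") from e
    except (TypeError, ValueError) as e:
        raise ValidationError(f"{path}: {e}") from e
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e
    raise ValidationError(f"{path}.kind: unknown distribution kind {kind!r}")


def _dist_to_dict(dist: SizeDistribution) -> dict:
    if dist.kind == "fixed":
        return {"kind": "fixed", "value": dist.minimum}
    out = {"kind": dist.kind, "minimum": dist.minimum, "maximum": dist.maximum}
    if dist.increment is not None:
        out["increment"] = dist.increment
    return out


def spec_from_dict(data: dict) -> TileSpec:
    """Build a validated TileSpec from parsed config data.

    Every failure names the offending field path.
    """
    if not isinstance(data, dict):
        raise ValidationError("spec root must be a mapping")
    try:
        tile = data["tile"]
        width = float(tile["width"])
        length = float(tile["length"])
        thickness = float(tile.get("thickness", 1.0))
    except KeyError as e:
        raise ValidationError(f"tile: missing field {e.args[0]!r}") from e
    except (TypeError, ValueError) as e:
        raise ValidationError(f"tile: {e}") from e

    raw_types = data.get("object_types")
    if not isinstance(raw_types, list) or not raw_types:
        raise ValidationError("object_types: must be a non-empty list")
    types = []
    for i, rt in enumerate(raw_types):
        path = f"object_types[{i}]"
        if not isinstance(rt, dict):
            raise ValidationError(f"{path}: expected a mapping")
        try:
            types.append(ObjectTypeSpec(
                type_id=str(rt["id"]),
                colour=str(rt.get("colour", "black")),
                shape=str(rt.get("shape", "circle")),
                footprint=_dist_from_dict(rt["footprint"], f"{path}.footprint"),
                depth=_dist_from_dict(rt["depth"], f"{path}.depth"),
            ))
        except KeyError as e:
            raise ValidationError(f"{path}: missing field {e.args[0]!r}") from e
        except ValidationError as e:
            if str(e).startswith(path):
                raise
            raise ValidationError(f"{path}: {e}") from e

    raw_p = data.get("abundances", "random")
    if isinstance(raw_p, str):
        if raw_p != "random":
            raise ValidationError(f"abundances: expected a list or 'random', got {raw_p!r}")
        abundances = None
    else:
        abundances = tuple(float(p) for p in raw_p)

    try:
        return TileSpec(
            tile_width=width, tile_length=length, tile_thickness=thickness,
            object_types=tuple(types), abundances=abundances,
            total_count=int(data.get("total_count", 0)),
            arrangement=str(data.get("arrangement", "random")),
            buffer=float(data.get("buffer", 0.0)),
            seed=int(data.get("seed", 0)),
            units=str(data.get("units", "units")),
        )
    except ValidationError as e:
        msg = str(e)
        if msg.startswith("abundances"):
            raise ValidationError(f"abundances: {msg}") from e
        raise


def spec_to_dict(spec: TileSpec) -> dict:
    return {
        "tile": {"width": spec.tile_width, "length": spec.tile_length,
                 "thickness": spec.tile_thickness},
        "units": spec.units,
        "object_types": [
            {"id": t.type_id, "colour": t.colour, "shape": t.shape,
             "footprint": _dist_to_dict(t.footprint),
             "depth": _dist_to_dict(t.depth)}
            for t in spec.object_types
        ],
        "abundances": list(spec.abundances) if spec.abundances is not None else "random",
        "total_count": int(spec.total_count),
        "arrangement": spec.arrangement,
        "buffer": spec.buffer,
        "seed": int(spec.seed),
    }


def read_spec(path) -> TileSpec:
    """Read and validate a tile spec from a YAML file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ValidationError(f"cannot parse spec file {path}: {e}") from e
    return spec_from_dict(data)


def write_spec(spec: TileSpec, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(spec_to_dict(spec), sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# design CSV (spreadsheet output)
# ---------------------------------------------------------------------------

def write_design_csv(design: TileDesign, path, include_report: bool = False) -> None:
    """Write one row per object, object_id order, full repr precision.

    With ``include_report`` a companion ``<path>.report.csv`` carries the
    complexity report as key,value rows.
    """
    lines = [",".join(CSV_HEADER)]
    for o in sorted(design.objects, key=lambda o: o.object_id):
        lines.append(",".join([
            str(o.object_id), o.type_id, design.shape_of(o),
            _num(o.centre_x), _num(o.centre_y),
            _num(o.footprint_size), _num(o.depth),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if include_report:
        rep = complexity_report(design)
        write_report_csv(rep, str(path) + ".report.csv")


def write_report_csv(rep: ComplexityReport, path) -> None:
    rows = [("metric", "value"),
            ("type_entropy_bits", _num(rep.type_entropy)),
            ("entropy_base", str(rep.entropy_base)),
            ("combination_count", str(rep.combination_count)),
            ("descriptor_count", str(rep.descriptor_count)),
            ("arrangement_rule", rep.arrangement_rule),
            ("density", str(rep.density)),
            ("comparable_key", rep.comparable_key)]
    for tid, dims in rep.size_level_counts.items():
        for dim, c in dims.items():
            rows.append((f"size_levels[{tid}][{dim}]", str(c)))
            rows.append((f"size_entropy_bits[{tid}][{dim}]",
                         _num(rep.size_entropy[tid][dim])))
    Path(path).write_text("\n".join(",".join(r) for r in rows) + "\n",
                          encoding="utf-8")


def read_design_csv(path, spec: TileSpec) -> TileDesign:
    """Rebuild a design from its CSV rows plus the spec that produced it."""
    objects = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_HEADER:
            raise ValidationError(
                f"unexpected CSV header {reader.fieldnames}; expected {CSV_HEADER}")
        for row in reader:
            objects.append(PlacedObject(
                object_id=int(row["object_id"]), type_id=row["type_id"],
                centre_x=float(row["centre_x"]), centre_y=float(row["centre_y"]),
                footprint_size=float(row["footprint_size"]),
                depth=float(row["depth"])))
    return TileDesign(spec=spec, objects=tuple(objects), seed=spec.seed)


# ---------------------------------------------------------------------------
# design JSON (lossless persistence)
# ---------------------------------------------------------------------------

def write_design_json(design: TileDesign, path) -> None:
    data = {
        "spec": spec_to_dict(design.spec),
        "units": design.spec.units,
        "objects": [
            {"object_id": o.object_id, "type_id": o.type_id,
             "centre_x": o.centre_x, "centre_y": o.centre_y,
             "footprint_size": o.footprint_size, "depth": o.depth}
            for o in design.objects
        ],
        "provenance": {"seed": design.seed,
                       "generator_version": design.generator_version},
        "edited": design.edited,
        "warnings": list(design.warnings),
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n", encoding="utf-8")


def read_design_json(path) -> TileDesign:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ValidationError(f"cannot parse design file {path}: {e}") from e
    spec = spec_from_dict(data["spec"])
    objects = tuple(PlacedObject(**o) for o in data.get("objects", []))
    prov = data.get("provenance", {})
    return TileDesign(spec=spec, objects=objects, seed=prov.get("seed"),
                      generator_version=prov.get("generator_version", ""),
                      edited=bool(data.get("edited", False)),
                      warnings=tuple(data.get("warnings", [])))


# ---------------------------------------------------------------------------
# DXF (minimal R12 ASCII)
# ---------------------------------------------------------------------------

def _dxf_pairs(pairs) -> list[str]:
    out = []
    for code, value in pairs:
        out.append(str(code))
        out.append(value if isinstance(value, str) else _num(value))
    return out


def write_design_dxf(design: TileDesign, path) -> None:
    """Emit a minimal R12 ASCII DXF of the design.

    Tile boundary: closed POLYLINE on layer ``TILE``.  Each circular pit: a
    CIRCLE on a layer named after its type, radius = footprint/2.  Each
    square pit: a closed POLYLINE on its type layer.  Pit depth goes into
    the entity thickness (group 39) and is mirrored as a TEXT entity
    ``<object_id>:depth=<depth>`` on layer ``DEPTH`` so it survives CAD
    tools that drop thickness.
    """
    W, L = design.spec.tile_width, design.spec.tile_length
    lines = _dxf_pairs([(0, "SECTION"), (2, "ENTITIES")])
    lines += _closed_polyline("TILE", [(0.0, 0.0), (W, 0.0), (W, L), (0.0, L)], 0.0)
    for o in sorted(design.objects, key=lambda o: o.object_id):
        if design.shape_of(o) == "circle":
            lines += _dxf_pairs([
                (0, "CIRCLE"), (8, o.type_id), (39, o.depth),
                (10, o.centre_x), (20, o.centre_y), (40, o.footprint_size / 2.0),
            ])
        else:
            h = o.footprint_size / 2.0
            corners = [(o.centre_x - h, o.centre_y - h), (o.centre_x + h, o.centre_y - h),
                       (o.centre_x + h, o.centre_y + h), (o.centre_x - h, o.centre_y + h)]
            lines += _closed_polyline(o.type_id, corners, o.depth)
        lines += _dxf_pairs([
            (0, "TEXT"), (8, "DEPTH"), (10, o.centre_x), (20, o.centre_y),
            (40, 1.0), (1, f"{o.object_id}:depth={_num(o.depth)}"),
        ])
    lines += _dxf_pairs([(0, "ENDSEC"), (0, "EOF")])
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _closed_polyline(layer: str, vertices, thickness: float) -> list[str]:
    pairs = [(0, "POLYLINE"), (8, layer), (66, 1), (70, 1)]
    if thickness:
        pairs.append((39, thickness))
    for x, y in vertices:
        pairs += [(0, "VERTEX"), (8, layer), (10, x), (20, y)]
    pairs += [(0, "SEQEND")]
    out = []
    for code, value in pairs:
        out.append(str(code))
        if isinstance(value, str):
            out.append(value)
        elif isinstance(value, int):
            out.append(str(value))
        else:
            out.append(_num(value))
    return out


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

def render_svg(design: TileDesign, options: ExportOptions | None = None,
               path=None) -> str:
    """Render the design as SVG 1.1; returns the markup, optionally writing it.

    1 user unit = 1 SVG unit; the y axis is flipped so the design's origin
    (lower-left) maps to SVG's bottom-left.  Object fill colours come from
    ``options.colour_map`` if given (which must then cover every type used),
    else from each type's declared colour.  Output is a pure function of
    (design, options).
    """
    options = options or ExportOptions(formats=("svg",))
    spec = design.spec
    W, L = spec.tile_width, spec.tile_length
    cmap = options.colour_map
    if cmap is not None:
        missing = sorted({o.type_id for o in design.objects} - set(cmap))
        if missing:
            raise ValidationError(f"colour_map missing type_id(s): {missing}")

    def colour(tid: str) -> str:
        return cmap[tid] if cmap is not None else spec.type_by_id(tid).colour

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_num(W)}" height="{_num(L)}" viewBox="0 0 {_num(W)} {_num(L)}">',
        f'<rect x="0" y="0" width="{_num(W)}" height="{_num(L)}" '
        f'fill="#e8e2d6" stroke="#333333" stroke-width="0.5"/>',
    ]
    for o in sorted(design.objects, key=lambda o: o.object_id):
        y_svg = L - o.centre_y
        fill = colour(o.type_id)
        if design.shape_of(o) == "circle":
            parts.append(
                f'<circle cx="{_num(o.centre_x)}" cy="{_num(y_svg)}" '
                f'r="{_num(o.footprint_size / 2.0)}" fill="{fill}"/>')
        else:
            h = o.footprint_size / 2.0
            parts.append(
                f'<rect x="{_num(o.centre_x - h)}" y="{_num(y_svg - h)}" '
                f'width="{_num(o.footprint_size)}" height="{_num(o.footprint_size)}" '
                f'fill="{fill}"/>')
    parts.append("</svg>")
    markup = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(markup, encoding="utf-8")
    return markup


# ---------------------------------------------------------------------------
# one-call export
# ---------------------------------------------------------------------------

def export_design(design: TileDesign, out_dir, basename: str = "design",
                  options: ExportOptions | None = None) -> dict[str, Path]:
    """Write the selected formats (plus the lossless JSON) into a directory.

    Returns the mapping format -> written path.
    """
    options = options or ExportOptions()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    json_path = out / f"{basename}.json"
    write_design_json(design, json_path)
    written["json"] = json_path
    if "csv" in options.formats:
        p = out / f"{basename}.csv"
        write_design_csv(design, p, include_report=options.include_report)
        written["csv"] = p
    if "dxf" in options.formats:
        p = out / f"{basename}.dxf"
        write_design_dxf(design, p)
        written["dxf"] = p
    if "svg" in options.formats:
        p = out / f"{basename}.svg"
        render_svg(design, options, p)
        written["svg"] = p
    return written
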