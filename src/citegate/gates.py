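"""The gating engine: geometries, Gate records, chains, schemes and replay.

A *gate* is one filtration event: a rectangle or polygon drawn on a 2-D
feature scatter (e.g. CD3 x CD4 on normalized ADT values) that splits an
input set of cell barcodes into the cells inside the boundary (the output)
and the rest. Each event is recorded as an immutable :class:`Gate` carrying
the axes, geometry, input/output barcodes and counts, so every downstream
cell set has a complete provenance trail.

Gates compose into a :class:`GateChain`: gate k draws from gate k-1's output
(the barcode-passing invariant), mirroring the iterative filtration of a
flow-cytometry workflow. Chains export in two forms — a full audit file
(barcodes, counts, timestamps) and a replayable *scheme* (axes + geometry
only) that can be re-executed on any container with the same features.

Membership rules (documented because replays must agree forever):

* boundary-inclusive everywhere — a point exactly on a gate edge is inside,
  for both rectangles and polygons (flow-cytometry convention);
* polygons use the even-odd ray-casting rule; the vertex list is implicitly
  closed; self-intersecting polygons are accepted with a warning;
* comparisons are exact floating point — membership is a geometric predicate,
  no epsilon.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .container import OmicsContainer
from .errors import (
    ChainingError,
    FeatureNotFoundError,
    SchemaError,
    SchemaVersionError,
    ValidationError,
)

__all__ = [
    "Rectangle",
    "Polygon",
    "point_in_geometry",
    "points_in_geometry",
    "Gate",
    "GateChain",
    "GateSpec",
    "GatingScheme",
    "apply_gate",
    "export_chain",
    "import_scheme",
    "replay",
    "summarize_chain",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rectangle:
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    kind: str = field(default="rectangle", init=False)

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate rectangle: x [{self.x_min}, {self.x_max}], "
                f"y [{self.y_min}, {self.y_max}]"
            )

    def to_dict(self) -> dict:
        return {
            "kind": "rectangle",
            "x_min": float(self.x_min),
            "x_max": float(self.x_max),
            "y_min": float(self.y_min),
            "y_max": float(self.y_max),
        }


@dataclass(frozen=True)
class Polygon:
    vertices: tuple[tuple[float, float], ...]
    kind: str = field(default="polygon", init=False)

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValidationError("polygon needs at least 3 vertices")
        if _self_intersects(verts):
            # signed area cancels across lobes, so skip the area check here
            warnings.warn(
                "self-intersecting polygon: membership uses the even-odd rule",
                UserWarning,
                stacklevel=3,
            )
        elif abs(_shoelace_area(np.asarray(verts))) == 0.0:
            raise ValidationError("polygon has zero area")

    def to_dict(self) -> dict:
        return {"kind": "polygon", "vertices": [[x, y] for x, y in self.vertices]}


Geometry = Rectangle | Polygon


def geometry_from_dict(d: dict) -> Geometry:
    try:
        kind = d["kind"]
    except (TypeError, KeyError):
        raise SchemaError("geometry is missing required key 'kind'") from None
    if kind == "rectangle":
        try:
            return Rectangle(d["x_min"], d["x_max"], d["y_min"], d["y_max"])
        except KeyError as exc:
            raise SchemaError(f"rectangle geometry missing key {exc.args[0]!r}") from None
    if kind == "polygon":
        if "vertices" not in d:
            raise SchemaError("polygon geometry missing key 'vertices'")
        return Polygon(tuple((v[0], v[1]) for v in d["vertices"]))
    raise SchemaError(f"unknown geometry kind {kind!r}")


def _shoelace_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _self_intersects(verts) -> bool:
    """O(n^2) proper-crossing test between non-adjacent edges."""
    v = np.asarray(verts, dtype=float)
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (1, n - 1):  # adjacent edges share a vertex
                continue
            p1, p2 = segs[i]
            q1, q2 = segs[j]
            d1, d2 = cross(q1, q2, p1), cross(q1, q2, p2)
            d3, d4 = cross(p1, p2, q1), cross(p1, p2, q2)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


def points_in_geometry(points, geometry: Geometry) -> np.ndarray:
    """Vectorized boundary-inclusive membership of an (n, 2) point array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    x, y = pts[:, 0], pts[:, 1]
    if isinstance(geometry, Rectangle):
        return (
            (geometry.x_min <= x)
            & (x <= geometry.x_max)
            & (geometry.y_min <= y)
            & (y <= geometry.y_max)
        )
    v = np.asarray(geometry.vertices, dtype=float)
    n = len(v)
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # exact on-segment test: collinear and inside the bounding box
        crossp = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        on_edge |= (
            (crossp == 0.0)
            & (np.minimum(x1, x2) <= x)
            & (x <= np.maximum(x1, x2))
            & (np.minimum(y1, y2) <= y)
            & (y <= np.maximum(y1, y2))
        )
        # even-odd ray casting, half-open in y so vertices count once
        crosses = (y1 > y) != (y2 > y)
        if crosses.any():
            t = (y[crosses] - y1) / (y2 - y1)
            xint = x1 + t * (x2 - x1)
            hit = np.zeros(len(pts), dtype=bool)
            hit[crosses] = x[crosses] < xint
            inside ^= hit
    return inside | on_edge


def point_in_geometry(point, geometry: Geometry) -> bool:
    """Boundary-inclusive membership of a single (x, y) point."""
    return bool(points_in_geometry(np.asarray(point, dtype=float)[None, :], geometry)[0])


# ---------------------------------------------------------------------------
# Gate and chain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gate:
    """One filtration event with full provenance.

    ``counter`` is the 1-based ordinal within a chain (None until appended);
    ``output_barcodes`` is always a subset of ``input_barcodes``, both kept in
    container order for byte-stable audit files.
    """

    label: str
    assay_x: str
    feature_x: str
    assay_y: str
    feature_y: str
    geometry: Geometry
    input_barcodes: tuple[str, ...]
    output_barcodes: tuple[str, ...]
    value_source: str = "normalized"
    created_at: str = ""
    counter: int | None = None

    def __post_init__(self) -> None:
        if not set(self.output_barcodes) <= set(self.input_barcodes):
            raise ValidationError("gate output barcodes are not a subset of its input")
        if not self.created_at:
            object.__setattr__(
                self,
                "created_at",
                _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            )

    @property
    def input_count(self) -> int:
        return len(self.input_barcodes)

    @property
    def output_count(self) -> int:
        return len(self.output_barcodes)

    def with_counter(self, counter: int) -> "Gate":
        g = Gate(
            label=self.label,
            assay_x=self.assay_x,
            feature_x=self.feature_x,
            assay_y=self.assay_y,
            feature_y=self.feature_y,
            geometry=self.geometry,
            input_barcodes=self.input_barcodes,
            output_barcodes=self.output_barcodes,
            value_source=self.value_source,
            created_at=self.created_at,
            counter=counter,
        )
        return g

    def spec(self) -> "GateSpec":
        return GateSpec(
            label=self.label,
            assay_x=self.assay_x,
            feature_x=self.feature_x,
            assay_y=self.assay_y,
            feature_y=self.feature_y,
            geometry=self.geometry,
        )

    def audit_dict(self) -> dict:
        return {
            "counter": self.counter,
            "label": self.label,
            "assay_x": self.assay_x,
            "feature_x": self.feature_x,
            "assay_y": self.assay_y,
            "feature_y": self.feature_y,
            "geometry": self.geometry.to_dict(),
            "value_source": self.value_source,
            "created_at": self.created_at,
            "input_count": self.input_count,
            "output_count": self.output_count,
            "input_barcodes": list(self.input_barcodes),
            "output_barcodes": list(self.output_barcodes),
        }


@dataclass(frozen=True)
class GateSpec:
    """The replayable part of a gate: axes + geometry + label, no barcodes."""

    label: str
    assay_x: str
    feature_x: str
    assay_y: str
    feature_y: str
    geometry: Geometry

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "assay_x": self.assay_x,
            "feature_x": self.feature_x,
            "assay_y": self.assay_y,
            "feature_y": self.feature_y,
            "geometry": self.geometry.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict, pos: int) -> "GateSpec":
        for key in ("label", "assay_x", "feature_x", "assay_y", "feature_y", "geometry"):
            if key not in d:
                raise SchemaError(f"gate {pos}: missing required key {key!r}")
        return cls(
            label=str(d["label"]),
            assay_x=str(d["assay_x"]),
            feature_x=str(d["feature_x"]),
            assay_y=str(d["assay_y"]),
            feature_y=str(d["feature_y"]),
            geometry=geometry_from_dict(d["geometry"]),
        )


@dataclass
class GatingScheme:
    """An ordered, replayable list of gate specifications."""

    name: str
    gates: list[GateSpec]
    normalization: dict | None = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "name": self.name,
            "normalization": self.normalization,
            "gates": [g.to_dict() for g in self.gates],
        }


class GateChain:
    """Ordered gates with the barcode-passing invariant.

    gate[k] must draw its input from gate[k-1]'s output (gate[0] from
    ``root_barcodes``); counters are assigned 1..N on append.
    """

    def __init__(
        self,
        root_barcodes,
        name: str = "chain",
        container_fingerprint: str | None = None,
        normalization: dict | None = None,
    ) -> None:
        self.root_barcodes: tuple[str, ...] = tuple(str(b) for b in root_barcodes)
        if not self.root_barcodes:
            raise ValidationError("chain root barcode set must be non-empty")
        self.name = name
        self.container_fingerprint = container_fingerprint
        self.normalization = normalization
        self.gates: list[Gate] = []

    def __len__(self) -> int:
        return len(self.gates)

    @property
    def current_barcodes(self) -> tuple[str, ...]:
        return self.gates[-1].output_barcodes if self.gates else self.root_barcodes

    def append(self, gate: Gate) -> "GateChain":
        expected = set(self.current_barcodes)
        got = set(gate.input_barcodes)
        if got != expected:
            raise ChainingError(
                f"gate {gate.label!r} input does not match the chain head: "
                f"{len(expected - got)} missing, {len(got - expected)} extra barcodes"
            )
        self.gates.append(gate.with_counter(len(self.gates) + 1))
        return self

    def validate(self) -> None:
        prev = set(self.root_barcodes)
        for k, g in enumerate(self.gates, start=1):
            if g.counter != k:
                raise ValidationError(f"gate {k} has counter {g.counter}")
            if set(g.input_barcodes) != prev:
                raise ChainingError(f"gate {k} breaks the barcode-passing invariant")
            if not set(g.output_barcodes) <= set(g.input_barcodes):
                raise ValidationError(f"gate {k} output is not a subset of its input")
            prev = set(g.output_barcodes)

    def scheme(self) -> GatingScheme:
        return GatingScheme(
            name=self.name,
            gates=[g.spec() for g in self.gates],
            normalization=self.normalization,
        )

    def audit_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "container_fingerprint": self.container_fingerprint,
            "normalization": self.normalization,
            "root_count": len(self.root_barcodes),
            "gates": [g.audit_dict() for g in self.gates],
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_gate(
    container: OmicsContainer,
    label: str,
    assay_x: str,
    feature_x: str,
    assay_y: str,
    feature_y: str,
    geometry: Geometry,
    input_barcodes=None,
    value_source: str = "auto",
) -> Gate:
    """Apply one gate: keep the input cells whose (x, y) lies in the geometry.

    ADT values are read from the normalized slot unless ``value_source="raw"``
    is requested explicitly; the source actually used is recorded on the Gate.
    An empty *output* is legal (warned); an empty *input* is an error.
    """
    if input_barcodes is None:
        input_barcodes = tuple(str(b) for b in container.barcodes)
    else:
        input_barcodes = tuple(str(b) for b in input_barcodes)
    if not input_barcodes:
        raise ValidationError("gate input barcode set is empty")

    # keep container order for byte-stable serialization
    pos = np.sort(container.barcode_positions(input_barcodes))
    ordered = tuple(str(b) for b in container.barcodes[pos])

    src_x = container.resolved_source(assay_x) if value_source == "auto" else value_source
    src_y = container.resolved_source(assay_y) if value_source == "auto" else value_source
    xv = container.feature_values(assay_x, feature_x, ordered, source=value_source)
    yv = container.feature_values(assay_y, feature_y, ordered, source=value_source)
    keep = points_in_geometry(np.column_stack([xv, yv]), geometry)
    out = tuple(b for b, k in zip(ordered, keep) if k)
    if not out:
        warnings.warn(
            f"gate {label!r} selected no cells", UserWarning, stacklevel=2
        )
    recorded = src_x if src_x == src_y else f"x:{src_x},y:{src_y}"
    return Gate(
        label=label,
        assay_x=assay_x,
        feature_x=feature_x,
        assay_y=assay_y,
        feature_y=feature_y,
        geometry=geometry,
        input_barcodes=ordered,
        output_barcodes=out,
        value_source=recorded,
    )


def export_chain(chain: GateChain, scheme_path, audit_path=None) -> tuple[Path, Path]:
    """Write the replayable scheme (YAML) and the full audit trail (JSON).

    The scheme omits barcodes entirely; the audit file records them per gate
    along with counts, timestamps and the container fingerprint. Returns the
    two paths. The scheme serialization is deterministic: exporting an
    imported scheme reproduces the file byte for byte.
    """
    chain.validate()
    scheme_path = Path(scheme_path)
    if audit_path is None:
        audit_path = scheme_path.with_suffix(".audit.json")
    audit_path = Path(audit_path)
    scheme_path.write_text(
        yaml.safe_dump(chain.scheme().to_dict(), sort_keys=False, default_flow_style=False)
    )
    audit_path.write_text(json.dumps(chain.audit_dict(), indent=2) + "\n")
    return scheme_path, audit_path


def export_scheme(scheme: GatingScheme, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(scheme.to_dict(), sort_keys=False, default_flow_style=False))
    return path


def import_scheme(path) -> GatingScheme:
    """Read a replayable scheme file, validating schema version and keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"scheme file {path} is not a mapping")
    if "schema_version" not in raw:
        raise SchemaError("scheme is missing required key 'schema_version'")
    found = raw["schema_version"]
    if found != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"scheme schema version {found!r} unsupported (expected {SCHEMA_VERSION})"
        )
    for key in ("name", "gates"):
        if key not in raw:
            raise SchemaError(f"scheme is missing required key {key!r}")
    gates = [GateSpec.from_dict(g, i + 1) for i, g in enumerate(raw["gates"])]
    return GatingScheme(
        name=str(raw["name"]),
        gates=gates,
        normalization=raw.get("normalization"),
        schema_version=found,
    )


def replay(
    scheme: GatingScheme,
    container: OmicsContainer,
    input_barcodes=None,
    value_source: str = "auto",
) -> GateChain:
    """Re-execute a scheme on a container, gate by gate.

    All features are resolved up front so a missing feature fails before any
    gate is applied. A normalization-record mismatch between the scheme and
    the container's ADT assay warns but proceeds (the values gate anyway).
    Deterministic: same scheme + same container => identical output sets.
    """
    for spec in scheme.gates:
        for assay, feature in ((spec.assay_x, spec.feature_x), (spec.assay_y, spec.feature_y)):
            if assay not in container.assays:
                raise FeatureNotFoundError(
                    f"scheme {scheme.name!r} needs assay {assay!r}, absent from container"
                )
            if feature not in container.assays[assay].feature_names:
                raise FeatureNotFoundError(
                    f"scheme {scheme.name!r} needs feature {feature!r} in assay {assay!r}"
                )
    adt = container.assays.get("ADT")
    if scheme.normalization and adt is not None and adt.normalization is not None:
        if dict(scheme.normalization) != dict(adt.normalization):
            warnings.warn(
                "scheme normalization record differs from the container's ADT "
                f"normalization ({scheme.normalization} vs {adt.normalization})",
                UserWarning,
                stacklevel=2,
            )
    if input_barcodes is None:
        input_barcodes = tuple(str(b) for b in container.barcodes)
    chain = GateChain(
        root_barcodes=input_barcodes,
        name=scheme.name,
        container_fingerprint=container.fingerprint(),
        normalization=scheme.normalization,
    )
    current = tuple(input_barcodes)
    for spec in scheme.gates:
        if not current:
            warnings.warn(
                f"replay of {scheme.name!r} stopped before {spec.label!r}: "
                "no cells left",
                UserWarning,
                stacklevel=2,
            )
            break
        gate = apply_gate(
            container,
            spec.label,
            spec.assay_x,
            spec.feature_x,
            spec.assay_y,
            spec.feature_y,
            spec.geometry,
            input_barcodes=current,
            value_source=value_source,
        )
        chain.append(gate)
        current = gate.output_barcodes
    return chain


def summarize_chain(chain: GateChain) -> pd.DataFrame:
    """Flow-style hierarchy table: per gate, counts and percent of parent/root."""
    rows = []
    root = len(chain.root_barcodes)
    for g in chain.gates:
        rows.append(
            {
                "counter": g.counter,
                "label": g.label,
                "input_count": g.input_count,
                "output_count": g.output_count,
                "pct_parent": 100.0 * g.output_count / g.input_count if g.input_count else 0.0,
                "pct_root": 100.0 * g.output_count / root if root else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["counter", "label", "input_count", "output_count", "pct_parent", "pct_root"],
    )
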