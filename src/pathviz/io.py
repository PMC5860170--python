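"""Reading and writing diagram files, and SVG rendering of classic diagrams.

The exchange format is a small, versioned JSON schema (documented in
``docs/format-diagram.md`` with a JSON-Schema file): top-level keys
``schemaVersion, pathwayId, canvas, nodes, edges, compartments, subpathways``.
Serialization is canonical — sorted keys, two-space indent — so that
write∘read is byte-stable and release artefacts diff cleanly.  Unknown
top-level keys are preserved for round-tripping.

Pathway hierarchies use a flat entry list with child identifier references
(``{"root": id, "entries": [{stableId, name, kind, children}]}``) so that
referential mistakes (cycles, dangling children) are detectable rather than
unrepresentable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from lxml import etree

from .highlight import (
    DEFAULT_FADE_END,
    DEFAULT_FADE_START,
    HighlightBox,
    fade_alpha,
)
from .model import (
    Compartment,
    Connector,
    ConnectorRole,
    Diagram,
    HierarchyKind,
    LineEnding,
    NodeGlyph,
    PathwayEntry,
    PathwayHierarchy,
    Point,
    ReactionEdge,
    Rect,
    SchemaClass,
    SubpathwayAssignment,
    validate_assignment,
    validate_diagram,
)
from .profiles import ColorProfile, svg_fill_attrs

SCHEMA_VERSION = 1
SVG_NS = "http://www.w3.org/2000/svg"
DEFAULT_LABEL_ZOOM_THRESHOLD = 0.5

_KNOWN_KEYS = {
    "schemaVersion",
    "pathwayId",
    "canvas",
    "nodes",
    "edges",
    "compartments",
    "subpathways",
}


class DiagramFormatError(ValueError):
    """Raised for malformed or unparseable input files."""


class InvalidDiagramError(ValueError):
    """Raised when a parsed file violates model invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid diagram: " + "; ".join(violations))


@dataclass
class DiagramDocument:
    schema_version: int
    diagram: Diagram
    subpathways: Optional[SubpathwayAssignment] = None
    extras: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# JSON (de)serialization helpers

def _rect_to_json(r: Rect) -> dict:
    # coerce to float so int-built rects serialize identically after re-read
    return {"x": float(r.x), "y": float(r.y), "w": float(r.w), "h": float(r.h)}


def _rect_from_json(d: dict) -> Rect:
    return Rect(float(d["x"]), float(d["y"]), float(d["w"]), float(d["h"]))


def _pt(p: Sequence[float]) -> Point:
    return (float(p[0]), float(p[1]))


def diagram_to_json(doc: DiagramDocument) -> dict:
    dg = doc.diagram
    out: dict[str, Any] = dict(doc.extras)
    out["schemaVersion"] = doc.schema_version
    out["pathwayId"] = dg.pathway_id
    out["canvas"] = _rect_to_json(dg.canvas)
    out["nodes"] = [
        {
            "id": n.id,
            "schemaClass": n.schema_class.value,
            "displayName": n.display_name,
            "bounds": _rect_to_json(n.bounds),
            **({"compartmentId": n.compartment_id} if n.compartment_id else {}),
        }
        for n in dg.nodes
    ]
    out["edges"] = [
        {
            "id": e.id,
            "reactionPoint": [float(v) for v in e.reaction_point],
            "segments": [[float(v) for v in p] for p in e.segments],
            "connectors": [
                {
                    "role": c.role.value,
                    "nodeId": c.node_id,
                    "points": [[float(v) for v in p] for p in c.points],
                    "ending": c.ending.value,
                }
                for c in e.connectors
            ],
        }
        for e in dg.edges
    ]
    out["compartments"] = [
        {
            "id": c.id,
            "name": c.name,
            "outer": _rect_to_json(c.outer),
            **({"inner": _rect_to_json(c.inner)} if c.inner else {}),
        }
        for c in dg.compartments
    ]
    if doc.subpathways is not None:
        sp = doc.subpathways
        out["subpathways"] = {
            "parentPathwayId": sp.parent_pathway_id,
            "groups": {k: sorted(v) for k, v in sp.groups.items()},
            "displayNames": dict(sp.display_names),
        }
    return out


def diagram_from_json(obj: dict) -> DiagramDocument:
    try:
        version = int(obj["schemaVersion"])
        if version != SCHEMA_VERSION:
            raise DiagramFormatError(f"unsupported schema version {version}")
        nodes = tuple(
            NodeGlyph(
                id=str(n["id"]),
                schema_class=SchemaClass(n["schemaClass"]),
                display_name=str(n["displayName"]),
                bounds=_rect_from_json(n["bounds"]),
                compartment_id=n.get("compartmentId"),
            )
            for n in obj["nodes"]
        )
        edges = tuple(
            ReactionEdge(
                id=str(e["id"]),
                reaction_point=_pt(e["reactionPoint"]),
                segments=tuple(_pt(p) for p in e["segments"]),
                connectors=tuple(
                    Connector(
                        role=ConnectorRole(c["role"]),
                        node_id=str(c["nodeId"]),
                        points=tuple(_pt(p) for p in c["points"]),
                        ending=LineEnding(c.get("ending", "none")),
                    )
                    for c in e["connectors"]
                ),
            )
            for e in obj["edges"]
        )
        compartments = tuple(
            Compartment(
                id=str(c["id"]),
                name=str(c["name"]),
                outer=_rect_from_json(c["outer"]),
                inner=_rect_from_json(c["inner"]) if "inner" in c else None,
            )
            for c in obj.get("compartments", [])
        )
        diagram = Diagram(
            pathway_id=str(obj["pathwayId"]),
            canvas=_rect_from_json(obj["canvas"]),
            nodes=nodes,
            edges=edges,
            compartments=compartments,
        )
        subpathways = None
        if "subpathways" in obj:
            sp = obj["subpathways"]
            subpathways = SubpathwayAssignment(
                parent_pathway_id=str(sp["parentPathwayId"]),
                groups={k: frozenset(v) for k, v in sp["groups"].items()},
                display_names=dict(sp.get("displayNames", {})),
            )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, DiagramFormatError):
            raise
        raise DiagramFormatError(f"malformed diagram file: {exc}") from exc

    extras = {k: v for k, v in obj.items() if k not in _KNOWN_KEYS}
    return DiagramDocument(version, diagram, subpathways, extras)


def _canonical_dump(obj: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_diagram(path: str) -> DiagramDocument:
    """Read and validate a diagram JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DiagramFormatError(
                f"malformed diagram file {path}: line {exc.lineno}: {exc.msg}"
            ) from exc
    doc = diagram_from_json(obj)
    violations = validate_diagram(doc.diagram)
    if doc.subpathways is not None:
        violations += validate_assignment(doc.diagram, doc.subpathways)
    if violations:
        raise InvalidDiagramError(violations)
    return doc


def write_diagram(doc: DiagramDocument, path: str) -> None:
    _canonical_dump(diagram_to_json(doc), path)


# ---------------------------------------------------------------------------
# Pathway hierarchy

def read_hierarchy(path: str) -> PathwayHierarchy:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DiagramFormatError(
                f"malformed hierarchy file {path}: line {exc.lineno}: {exc.msg}"
            ) from exc
    return hierarchy_from_json(obj)


def hierarchy_from_json(obj: dict) -> PathwayHierarchy:
    try:
        raw = {str(e["stableId"]): e for e in obj["entries"]}
        if len(raw) != len(obj["entries"]):
            raise DiagramFormatError("duplicate stable identifier in hierarchy")
        root_id = str(obj["root"])
    except (KeyError, TypeError) as exc:
        raise DiagramFormatError(f"malformed hierarchy file: {exc}") from exc

    building: set[str] = set()
    built: dict[str, PathwayEntry] = {}

    def build(sid: str) -> PathwayEntry:
        if sid in building:
            raise DiagramFormatError(f"hierarchy cycle involving '{sid}'")
        if sid in built:
            raise DiagramFormatError(f"entry '{sid}' has multiple parents")
        if sid not in raw:
            raise DiagramFormatError(f"hierarchy references unknown entry '{sid}'")
        e = raw[sid]
        building.add(sid)
        try:
            kind = HierarchyKind(e["kind"])
            children = [build(str(c)) for c in e.get("children", [])]
        except (KeyError, ValueError) as exc:
            raise DiagramFormatError(f"malformed hierarchy entry '{sid}': {exc}") from exc
        finally:
            building.discard(sid)
        if kind is HierarchyKind.LOWER_LEVEL and children:
            raise DiagramFormatError(f"lower-level entry '{sid}' has children")
        entry = PathwayEntry(sid, str(e["name"]), kind, children)
        built[sid] = entry
        return entry

    return PathwayHierarchy(build(root_id))


def hierarchy_to_json(h: PathwayHierarchy) -> dict:
    entries = []
    for e in h.walk():
        entries.append(
            {
                "stableId": e.stable_id,
                "name": e.name,
                "kind": e.kind.value,
                "children": [c.stable_id for c in e.children],
            }
        )
    entries.sort(key=lambda d: d["stableId"])
    return {"root": h.root.stable_id, "entries": entries}


def write_hierarchy(h: PathwayHierarchy, path: str) -> None:
    _canonical_dump(hierarchy_to_json(h), path)


# ---------------------------------------------------------------------------
# Colour profile JSON

def read_color_profile(path: str) -> ColorProfile:
    """Load a colour profile from a JSON config file."""
    with open(path, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        return ColorProfile(
            name=str(obj["name"]),
            node_fill={SchemaClass(k): v for k, v in obj["nodeFill"].items()},
            node_stroke={SchemaClass(k): v for k, v in obj["nodeStroke"].items()},
            subpathway_palette=tuple(obj["subpathwayPalette"]),
            overlay_gradient=tuple(obj["overlayGradient"]),
            not_significant_color=str(obj["notSignificantColor"]),
            hit_bar_color=str(obj["hitBarColor"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DiagramFormatError(f"malformed colour profile: {exc}") from exc


# ---------------------------------------------------------------------------
# SVG rendering

def _el(parent, tag: str, **attrs) -> etree._Element:
    e = etree.SubElement(parent, f"{{{SVG_NS}}}{tag}")
    for k, v in attrs.items():
        e.set(k.replace("_", "-"), str(v))
    return e


def _poly_points(points: Sequence[Point]) -> str:
    return " ".join(f"{x:g},{y:g}" for x, y in points)


def _ending_glyph(parent, conn: Connector, stroke: str) -> None:
    """Draw the SBGN line ending at the appropriate connector end."""
    pts = conn.points
    if conn.ending is LineEnding.ARROW and len(pts) >= 2:
        # product arrow points at the node (first point of the polyline)
        tip = pts[0]
        ref = pts[1]
        dx, dy = tip[0] - ref[0], tip[1] - ref[1]
        L = math.hypot(dx, dy) or 1.0
        ux, uy = dx / L, dy / L
        px, py = -uy, ux
        base = (tip[0] - 8 * ux, tip[1] - 8 * uy)
        tri = [tip, (base[0] + 3 * px, base[1] + 3 * py), (base[0] - 3 * px, base[1] - 3 * py)]
        _el(parent, "polygon", points=_poly_points(tri), fill=stroke)
    elif conn.ending is LineEnding.CIRCLE:
        cx, cy = pts[-1]
        _el(parent, "circle", cx=f"{cx:g}", cy=f"{cy:g}", r="4", fill="none", stroke=stroke)
    elif conn.ending is LineEnding.BAR and len(pts) >= 2:
        end = pts[-1]
        ref = pts[-2]
        dx, dy = end[0] - ref[0], end[1] - ref[1]
        L = math.hypot(dx, dy) or 1.0
        px, py = -dy / L, dx / L
        _el(
            parent,
            "line",
            x1=f"{end[0] + 5 * px:g}",
            y1=f"{end[1] + 5 * py:g}",
            x2=f"{end[0] - 5 * px:g}",
            y2=f"{end[1] - 5 * py:g}",
            stroke=stroke,
            stroke_width="2",
        )


def _render_node_shape(parent, node: NodeGlyph, profile: ColorProfile):
    b = node.bounds
    fill = profile.node_fill[node.schema_class]
    stroke = profile.node_stroke[node.schema_class]
    common = dict(fill=fill, stroke=stroke)
    if node.schema_class is SchemaClass.CHEMICAL:
        cx, cy = b.center
        return _el(
            parent, "ellipse", id=node.id,
            cx=f"{cx:g}", cy=f"{cy:g}", rx=f"{b.w / 2:g}", ry=f"{b.h / 2:g}", **common,
        )
    rx = {
        SchemaClass.PROTEIN: 8,
        SchemaClass.ENTITY_SET: 12,
        SchemaClass.COMPLEX: 4,
    }.get(node.schema_class, 0)
    attrs = dict(x=f"{b.x:g}", y=f"{b.y:g}", width=f"{b.w:g}", height=f"{b.h:g}", **common)
    if rx:
        attrs["rx"] = str(rx)
    return _el(parent, "rect", id=node.id, **attrs)


def render_svg(
    diagram: Diagram,
    profile: ColorProfile,
    *,
    show_labels: bool = True,
    highlights: Optional[Sequence[HighlightBox]] = None,
    zoom: float = 1.0,
    label_zoom_threshold: float = DEFAULT_LABEL_ZOOM_THRESHOLD,
    fade_start: float = DEFAULT_FADE_START,
    fade_end: float = DEFAULT_FADE_END,
) -> str:
    """Render a classic diagram to SVG 1.1.

    Every node, edge and compartment becomes one element carrying its stable
    identifier as the element id.  Entity text is omitted below the label
    zoom threshold (zoomed-out views drop the in-icon text).  Highlight
    boxes, when given, are drawn beneath edges and nodes with opacity
    ``fade_alpha(zoom)`` so they vanish as the user zooms into reactions.
    """
    if zoom <= 0:
        raise ValueError("zoom must be positive")
    c = diagram.canvas
    root = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS},
        version="1.1",
        width=f"{c.w * zoom:g}",
        height=f"{c.h * zoom:g}",
        viewBox=f"{c.x:g} {c.y:g} {c.w:g} {c.h:g}",
    )
    labels_on = show_labels and zoom >= label_zoom_threshold

    comp_g = _el(root, "g", **{"class": "compartments"})
    for comp in diagram.compartments:
        g = _el(comp_g, "g", id=comp.id)
        o = comp.outer
        _el(g, "rect", x=f"{o.x:g}", y=f"{o.y:g}", width=f"{o.w:g}", height=f"{o.h:g}",
            fill="#F5F0D7", fill_opacity="0.5", stroke="#B4A764", rx="12")
        if comp.inner is not None:
            i = comp.inner
            _el(g, "rect", x=f"{i.x:g}", y=f"{i.y:g}", width=f"{i.w:g}", height=f"{i.h:g}",
                fill="none", stroke="#B4A764", rx="10")
        t = _el(g, "text", x=f"{o.x + 6:g}", y=f"{o.bottom - 6:g}",
                font_size="12", fill="#8A7D43", **{"class": "compartment-label"})
        t.text = comp.name

    if highlights:
        alpha = fade_alpha(zoom, fade_start, fade_end)
        hg = _el(root, "g", **{"class": "highlights", "opacity": f"{alpha:g}"})
        for box in highlights:
            g = _el(hg, "g", id=f"highlight-{box.subpathway_id}")
            b = box.box
            attrs = svg_fill_attrs(box.fill)
            _el(g, "rect", x=f"{b.x:g}", y=f"{b.y:g}", width=f"{b.w:g}",
                height=f"{b.h:g}", rx="6", **attrs, **{"class": "highlight-box"})
            if box.label_rect is not None and box.font_size is not None:
                lr = box.label_rect
                if box.overlay_fill is not None:
                    oa = svg_fill_attrs(box.overlay_fill)
                    _el(g, "rect", x=f"{lr.x:g}", y=f"{lr.y:g}", width=f"{lr.w:g}",
                        height=f"{lr.h:g}", **oa, **{"class": "overlay-rect"})
                t = _el(g, "text", x=f"{lr.x:g}",
                        y=f"{lr.y + box.font_size:g}",
                        font_size=f"{box.font_size:g}", fill="#333333",
                        **{"class": "highlight-label"})
                t.text = box.label_text
                if box.bar is not None:
                    bar = box.bar
                    _el(g, "rect", x=f"{bar.x:g}", y=f"{bar.y:g}",
                        width=f"{bar.w:g}", height=f"{bar.h:g}",
                        fill=profile.hit_bar_color, **{"class": "hit-bar"})
                if box.annotation:
                    at = _el(g, "text", x=f"{lr.x:g}",
                             y=f"{lr.y + box.font_size + 10:g}",
                             font_size="8", fill="#333333",
                             **{"class": "overlay-annotation"})
                    at.text = box.annotation

    edge_g = _el(root, "g", **{"class": "edges"})
    for edge in diagram.edges:
        g = _el(edge_g, "g", id=edge.id)
        stroke = "#404040"
        if len(edge.segments) >= 2:
            _el(g, "polyline", points=_poly_points(edge.segments),
                fill="none", stroke=stroke)
        for conn in edge.connectors:
            if len(conn.points) >= 2:
                _el(g, "polyline", points=_poly_points(conn.points),
                    fill="none", stroke=stroke)
            _ending_glyph(g, conn, stroke)
        rx_, ry_ = edge.reaction_point
        _el(g, "rect", x=f"{rx_ - 4:g}", y=f"{ry_ - 4:g}", width="8", height="8",
            fill="#FFFFFF", stroke=stroke)

    node_g = _el(root, "g", **{"class": "nodes"})
    for node in diagram.nodes:
        _render_node_shape(node_g, node, profile)

    if labels_on:
        label_g = _el(root, "g", **{"class": "labels"})
        for node in diagram.nodes:
            cx, cy = node.bounds.center
            t = _el(label_g, "text", x=f"{cx:g}", y=f"{cy:g}",
                    text_anchor="middle", dominant_baseline="middle",
                    font_size="11", fill="#1A1A1A")
            t.text = node.display_name

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


def render_thumbnail(diagram: Diagram, max_edge: float) -> str:
    """Small text-free preview of a diagram for the viewport corner.

    The viewBox equals the diagram canvas; width/height scale the longer
    canvas edge to ``max_edge`` preserving aspect ratio.
    """
    if max_edge < 16:
        raise ValueError("thumbnail too small (max_edge must be >= 16)")
    c = diagram.canvas
    scale = max_edge / max(c.w, c.h)
    root = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS},
        version="1.1",
        # full-precision width/height so the aspect ratio is preserved exactly
        width=str(c.w * scale),
        height=str(c.h * scale),
        viewBox=f"{c.x:g} {c.y:g} {c.w:g} {c.h:g}",
    )
    for comp in diagram.compartments:
        o = comp.outer
        _el(root, "rect", x=f"{o.x:g}", y=f"{o.y:g}", width=f"{o.w:g}",
            height=f"{o.h:g}", fill="#F5F0D7", stroke="#B4A764")
    for edge in diagram.edges:
        if len(edge.segments) >= 2:
            _el(root, "polyline", points=_poly_points(edge.segments),
                fill="none", stroke="#808080")
        for conn in edge.connectors:
            if len(conn.points) >= 2:
                _el(root, "polyline", points=_poly_points(conn.points),
                    fill="none", stroke="#808080")
    for node in diagram.nodes:
        b = node.bounds
        _el(root, "rect", x=f"{b.x:g}", y=f"{b.y:g}", width=f"{b.w:g}",
            height=f"{b.h:g}", fill="#9FB8CE")
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")
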