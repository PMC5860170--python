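"""Interactive textbook-style high-level pathway diagrams (EHLDs).

An EHLD is an ordinary SVG 1.1 illustration in which three kinds of technical
annotation, keyed by the stable pathway identifier in the element id, make
subpathways interactive:

* ``REGION-<stableId>`` — the clickable area representing the subpathway,
* ``TEXT-<stableId>``   — the text element holding the subpathway name,
* ``OVERLAY-<stableId>`` — the element to be covered by analysis results.

Every element carrying none of these annotations is a decoration and is never
touched by any operation here.  The id prefixes are configurable
(:class:`AnnotationPrefixes`) to accommodate other dialects; the convention is
documented in ``docs/format-ehld.md``.

Hit-testing uses exact containment for rect/circle/ellipse/polygon elements
and the bounding box for path elements (full Bézier containment is
deliberately out of scope); the topmost hit is the last in document order.
Interaction states (hover highlight, selection, flagging) are rendered with
explicit attribute edits — not CSS classes — so exported files look the same
in any SVG viewer, and the original attribute values are stashed on the
element so returning to the normal state restores the document exactly.
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon

from .model import Point, Rect

logger = logging.getLogger(__name__)

SVG_NS = "http://www.w3.org/2000/svg"
OVERLAY_GROUP_ID = "analysis-overlay"

_ORIG_ATTR = "data-pv-orig"
_STATE_ATTR = "data-pv-state"
_FLAG_PREFIX = "FLAG-"

#: Explicit styling per interaction state (attribute → value).
STATE_STYLES: dict[str, dict[str, str]] = {
    "highlighted": {"stroke": "#FFA500", "stroke-width": "3"},
    "selected": {"stroke": "#1E90FF", "stroke-width": "3"},
}

REGION_STATES = ("normal", "highlighted", "selected", "flagged")


class EhldError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationPrefixes:
    region: str = "REGION-"
    label: str = "TEXT-"
    overlay: str = "OVERLAY-"


@dataclass
class ActiveRegion:
    """The (region, label, overlay-target) triple of one subpathway."""

    pathway_id: str
    region_ref: etree._Element
    label_ref: Optional[etree._Element] = None
    overlay_ref: Optional[etree._Element] = None


@dataclass
class EhldDocument:
    root: etree._Element
    regions: list[ActiveRegion]
    canvas: Rect
    prefixes: AnnotationPrefixes = field(default_factory=AnnotationPrefixes)

    def region(self, pathway_id: str) -> ActiveRegion:
        for r in self.regions:
            if r.pathway_id == pathway_id:
                return r
        raise EhldError(f"no such region '{pathway_id}'")


# ---------------------------------------------------------------------------
# Geometry of SVG elements

_FLOAT_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _floats(s: str) -> list[float]:
    return [float(m) for m in _FLOAT_RE.findall(s)]


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _path_points(d: str) -> list[Point]:
    """Every on-curve and control point of a path, for bounding-box purposes.

    Handles absolute and relative M/L/H/V/C/S/Q/T commands; arcs contribute
    their endpoint only.  Control points can only enlarge the box, so the
    result is a conservative cover of the drawn path.
    """
    tokens = re.findall(r"[MmLlHhVvCcSsQqTtAaZz]|" + _FLOAT_RE.pattern, d)
    pts: list[Point] = []
    cx = cy = sx = sy = 0.0
    i = 0
    cmd = ""
    while i < len(tokens):
        if tokens[i].isalpha():
            cmd = tokens[i]
            i += 1
            if cmd in "Zz":
                cx, cy = sx, sy
                continue
        rel = cmd.islower()
        c = cmd.upper()

        def take(n: int) -> list[float]:
            nonlocal i
            vals = [float(tokens[i + k]) for k in range(n)]
            i += n
            return vals

        if c == "M" or c == "L" or c == "T":
            x, y = take(2)
            if rel:
                x, y = cx + x, cy + y
            cx, cy = x, y
            if c == "M":
                sx, sy = x, y
                cmd = "l" if rel else "L"  # implicit lineto after moveto
            pts.append((x, y))
        elif c == "H":
            (x,) = take(1)
            cx = cx + x if rel else x
            pts.append((cx, cy))
        elif c == "V":
            (y,) = take(1)
            cy = cy + y if rel else y
            pts.append((cx, cy))
        elif c == "C":
            vals = take(6)
            coords = [(vals[k], vals[k + 1]) for k in (0, 2, 4)]
            if rel:
                coords = [(cx + x, cy + y) for x, y in coords]
            pts.extend(coords)
            cx, cy = coords[-1]
        elif c in ("S", "Q"):
            vals = take(4)
            coords = [(vals[0], vals[1]), (vals[2], vals[3])]
            if rel:
                coords = [(cx + x, cy + y) for x, y in coords]
            pts.extend(coords)
            cx, cy = coords[-1]
        elif c == "A":
            vals = take(7)
            x, y = vals[5], vals[6]
            if rel:
                x, y = cx + x, cy + y
            cx, cy = x, y
            pts.append((x, y))
        else:
            i += 1  # unknown token: skip defensively
    return pts


def element_bbox(el: etree._Element) -> Optional[Rect]:
    """Untransformed bounding box of a shape or group element."""
    tag = _local(el)
    get = lambda k, d="0": float(el.get(k, d))
    if tag == "rect":
        return Rect(get("x"), get("y"), get("width"), get("height"))
    if tag == "circle":
        r = get("r")
        return Rect(get("cx") - r, get("cy") - r, 2 * r, 2 * r)
    if tag == "ellipse":
        rx, ry = get("rx"), get("ry")
        return Rect(get("cx") - rx, get("cy") - ry, 2 * rx, 2 * ry)
    if tag in ("polygon", "polyline"):
        vals = _floats(el.get("points", ""))
        pts = list(zip(vals[::2], vals[1::2]))
        if not pts:
            return None
        xs, ys = [p[0] for p in pts], [p[1] for p in pts]
        return Rect(min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))
    if tag == "path":
        pts = _path_points(el.get("d", ""))
        if not pts:
            return None
        xs, ys = [p[0] for p in pts], [p[1] for p in pts]
        return Rect(min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))
    if tag == "text":
        return Rect(get("x"), get("y"), 0, 0)
    if tag == "g":
        boxes = [b for b in (element_bbox(c) for c in el) if b is not None]
        if not boxes:
            return None
        x = min(b.x for b in boxes)
        y = min(b.y for b in boxes)
        return Rect(x, y, max(b.right for b in boxes) - x, max(b.bottom for b in boxes) - y)
    return None


def element_contains(el: etree._Element, point: Point) -> bool:
    """Exact containment for basic shapes; bbox for paths; union for groups."""
    tag = _local(el)
    px, py = point
    get = lambda k, d="0": float(el.get(k, d))
    if tag == "rect":
        return Rect(get("x"), get("y"), get("width"), get("height")).contains_point(point)
    if tag == "circle":
        r = get("r")
        return (px - get("cx")) ** 2 + (py - get("cy")) ** 2 <= r * r
    if tag == "ellipse":
        rx, ry = get("rx"), get("ry")
        if rx <= 0 or ry <= 0:
            return False
        return ((px - get("cx")) / rx) ** 2 + ((py - get("cy")) / ry) ** 2 <= 1.0
    if tag == "polygon":
        vals = _floats(el.get("points", ""))
        pts = list(zip(vals[::2], vals[1::2]))
        if len(pts) < 3:
            return False
        return ShapelyPolygon(pts).buffer(0).covers(ShapelyPoint(px, py))
    if tag == "path":
        bbox = element_bbox(el)
        return bbox is not None and bbox.contains_point(point)
    if tag == "g":
        return any(element_contains(c, point) for c in el)
    return False


# ---------------------------------------------------------------------------
# Parsing

def parse_ehld(
    svg_text: str | bytes, prefixes: AnnotationPrefixes = AnnotationPrefixes()
) -> EhldDocument:
    """Parse an EHLD SVG and index its active regions.

    Regions are discovered by the element-id annotation convention.  A
    duplicate region id is an error; a region missing its label or overlay
    element is reported as a warning and kept as a partial region.
    """
    data = svg_text.encode("utf-8") if isinstance(svg_text, str) else svg_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise EhldError(f"malformed SVG: {exc}") from exc
    if _local(root) != "svg":
        raise EhldError("not an SVG document")
    viewbox = root.get("viewBox")
    if not viewbox:
        raise EhldError("no canvas: SVG lacks a viewBox")
    vb = _floats(viewbox)
    if len(vb) != 4:
        raise EhldError("no canvas: viewBox malformed")
    canvas = Rect(vb[0], vb[1], vb[2], vb[3])

    region_els: dict[str, etree._Element] = {}
    label_els: dict[str, etree._Element] = {}
    overlay_els: dict[str, etree._Element] = {}
    order: list[str] = []
    for el in root.iter():
        eid = el.get("id")
        if not eid:
            continue
        if eid.startswith(prefixes.region):
            pid = eid[len(prefixes.region):]
            if pid in region_els:
                raise EhldError(f"duplicate region id '{pid}'")
            region_els[pid] = el
            order.append(pid)
        elif eid.startswith(prefixes.label):
            label_els[eid[len(prefixes.label):]] = el
        elif eid.startswith(prefixes.overlay):
            overlay_els[eid[len(prefixes.overlay):]] = el

    regions: list[ActiveRegion] = []
    for pid in order:
        label = label_els.get(pid)
        overlay = overlay_els.get(pid)
        if label is None or overlay is None:
            missing = [
                name
                for name, el in (("label", label), ("overlay", overlay))
                if el is None
            ]
            logger.warning(
                "region '%s' missing %s annotation(s); partial active region",
                pid, "/".join(missing),
            )
        regions.append(ActiveRegion(pid, region_els[pid], label, overlay))
    return EhldDocument(root, regions, canvas, prefixes)


# ---------------------------------------------------------------------------
# Interaction

def hit_test(doc: EhldDocument, point: Point) -> Optional[str]:
    """Pathway id of the topmost active region under a point, else None.

    Decorations never hit; ties are resolved to the region latest in document
    order (the one painted on top).
    """
    if not doc.canvas.contains_point(point):
        raise EhldError(f"out of canvas: {point}")
    hit: Optional[str] = None
    for region in doc.regions:  # document order; later regions paint on top
        if element_contains(region.region_ref, point):
            hit = region.pathway_id
    return hit


def _clear_state(doc: EhldDocument, region: ActiveRegion) -> None:
    el = region.region_ref
    orig = el.get(_ORIG_ATTR)
    if orig is not None:
        for attr, value in json.loads(orig).items():
            if value is None:
                el.attrib.pop(attr, None)
            else:
                el.set(attr, value)
        el.attrib.pop(_ORIG_ATTR, None)
    el.attrib.pop(_STATE_ATTR, None)
    flag_id = _FLAG_PREFIX + region.pathway_id
    for flag in doc.root.iter():
        if flag.get("id") == flag_id:
            flag.getparent().remove(flag)
            break


def set_region_state(doc: EhldDocument, pathway_id: str, state: str) -> EhldDocument:
    """Set the interaction state of a region (in place; returns the document).

    Idempotent per state; ``normal`` restores the original attributes so the
    serialized document equals the untouched original.
    """
    if state not in REGION_STATES:
        raise EhldError(f"unknown state '{state}'")
    region = doc.region(pathway_id)
    _clear_state(doc, region)
    if state == "normal":
        return doc
    el = region.region_ref
    if state in STATE_STYLES:
        style = STATE_STYLES[state]
        el.set(_ORIG_ATTR, json.dumps({a: el.get(a) for a in style}, sort_keys=True))
        for attr, value in style.items():
            el.set(attr, value)
    else:  # flagged: a marker dot at the region's top-right corner
        el.set(_ORIG_ATTR, json.dumps({}))
        bbox = element_bbox(el) or doc.canvas
        marker = etree.SubElement(doc.root, f"{{{SVG_NS}}}circle")
        marker.set("id", _FLAG_PREFIX + pathway_id)
        marker.set("cx", f"{bbox.right:g}")
        marker.set("cy", f"{bbox.y:g}")
        marker.set("r", "6")
        marker.set("fill", "#FF00FF")
        marker.set("stroke", "#FFFFFF")
    el.set(_STATE_ATTR, state)
    return doc


# ---------------------------------------------------------------------------
# Export

def export_svg(doc: EhldDocument, include_overlay: bool = True) -> str:
    """Serialize the EHLD, optionally stripping the analysis overlay group."""
    root = copy.deepcopy(doc.root)
    if not include_overlay:
        for el in list(root.iter(f"{{{SVG_NS}}}g")):
            if el.get("id") == OVERLAY_GROUP_ID:
                el.getparent().remove(el)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def canonical_svg(svg_text: str | bytes) -> bytes:
    """Canonical (C14N) form of an SVG document, for equality comparisons."""
    data = svg_text.encode("utf-8") if isinstance(svg_text, str) else svg_text
    tree = etree.fromstring(data).getroottree()
    return etree.tostring(tree, method="c14n2")
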