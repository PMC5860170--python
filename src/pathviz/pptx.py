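"""Editable PPTX export of classic pathway diagrams.

A diagram is exported as a single-slide OOXML PresentationML package in
which every glyph is an autoshape and every reaction line is a chain of
*connectors* whose endpoints are **references to shape ids, never bare
coordinates** — so when a glyph is moved in a presentation editor, every
attached line follows.  Polyline bends are realised as *invisible anchor
points*: tiny shapes with no line and no fill that join the straight
connector segments of one reaction into a movable whole.  Shapes that
visually define reaction properties (catalysis circles, inhibition bars)
are grouped with their adjacent connector segment so the ending travels
with its line.

The OOXML package is written directly (content types, relationships, slide,
layout, master, theme) with a fixed canvas-unit→EMU scale of 9525 (96 canvas
units per inch).  Zip entries carry a fixed timestamp so identical graphs
produce byte-identical files.
"""

from __future__ import annotations

import math
import zipfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

from lxml import etree

from .model import (
    Connector,
    ConnectorRole,
    Diagram,
    LineEnding,
    NodeGlyph,
    Point,
    ReactionEdge,
    Rect,
    SchemaClass,
    validate_diagram,
    DEFAULT_ENDPOINT_TOLERANCE,
)
from .profiles import ColorProfile, parse_color

EMU_PER_UNIT = 9525  # 96 canvas units per inch, 914400 EMU per inch

NS_P = "http://schemas.openxmlformats.org/presentationml/2006/main"
NS_A = "http://schemas.openxmlformats.org/drawingml/2006/main"
NS_R = "http://schemas.openxmlformats.org/officeDocument/2006/relationships"
NS_CT = "http://schemas.openxmlformats.org/package/2006/content-types"
NS_REL = "http://schemas.openxmlformats.org/package/2006/relationships"

ANCHOR_SIZE = 2.0  # canvas units; invisible but selectable in editors
CENTER_SIZE = 8.0

_GEOMETRY_BY_CLASS = {
    SchemaClass.PROTEIN: "roundRect",
    SchemaClass.CHEMICAL: "ellipse",
    SchemaClass.COMPLEX: "rect",
    SchemaClass.ENTITY_SET: "hexagon",
    SchemaClass.GENE: "rect",
    SchemaClass.RNA: "rect",
    SchemaClass.PROCESS_NODE: "rect",
}


class PptxExportError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorPoint:
    """Invisible joint between the segments of one reaction line."""

    id: int
    position: Point


@dataclass(frozen=True)
class ShapeSpec:
    id: int
    name: str
    kind: str  # node | center | anchor | decoration
    rect: Rect
    geometry: str = "rect"
    fill: Optional[str] = None  # None -> noFill
    stroke: Optional[str] = None  # None -> no line
    text: Optional[str] = None


@dataclass(frozen=True)
class ConnectorSpec:
    """A straight connector attached by reference at both ends."""

    id: int
    name: str
    from_id: int
    to_id: int
    head_end: str = "none"  # decoration at the start ("triangle", "oval", "none")
    tail_end: str = "none"
    dashed: bool = False
    stroke: str = "#404040"


@dataclass(frozen=True)
class AnchoredShapeGraph:
    canvas: Rect
    shapes: tuple[ShapeSpec, ...]
    connectors: tuple[ConnectorSpec, ...]
    groups: tuple[frozenset[int], ...] = ()

    def shape_by_id(self) -> dict[int, ShapeSpec]:
        return {s.id: s for s in self.shapes}

    def count(self, kind: str) -> int:
        return sum(1 for s in self.shapes if s.kind == kind)


# ---------------------------------------------------------------------------
# Graph construction

def _dist(a: Point, b: Point) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


class _Builder:
    def __init__(self, diagram: Diagram, profile: ColorProfile, tol: float):
        self.diagram = diagram
        self.profile = profile
        self.tol = tol
        self.next_id = 2  # id 1 belongs to the slide's shape tree root
        self.shapes: list[ShapeSpec] = []
        self.connectors: list[ConnectorSpec] = []
        self.groups: list[frozenset[int]] = []
        self.node_shape: dict[str, int] = {}

    def take_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def add_anchor(self, position: Point) -> int:
        anchor = AnchorPoint(self.take_id(), position)
        self.shapes.append(
            ShapeSpec(
                id=anchor.id,
                name=f"anchor-{anchor.id}",
                kind="anchor",
                rect=Rect(
                    position[0] - ANCHOR_SIZE / 2,
                    position[1] - ANCHOR_SIZE / 2,
                    ANCHOR_SIZE,
                    ANCHOR_SIZE,
                ),
                geometry="rect",
                fill=None,
                stroke=None,
            )
        )
        return anchor.id

    def resolve_endpoint(self, p: Point, edge: ReactionEdge, center_id: int) -> int:
        """Map a polyline endpoint to the shape it touches, else a new anchor."""
        if _dist(p, edge.reaction_point) <= max(self.tol, CENTER_SIZE / 2):
            return center_id
        for node in self.diagram.nodes:
            if node.bounds.padded(self.tol).contains_point(p):
                return self.node_shape[node.id]
        return self.add_anchor(p)

    def chain(
        self,
        endpoint_ids: tuple[int, int],
        points: Sequence[Point],
        name: str,
        head_end: str = "none",
        tail_end: str = "none",
    ) -> list[int]:
        """One connector per polyline segment, interior bends as anchors.

        ``endpoint_ids`` are the shape ids for the first and last point; the
        decorated end styles go on the first / last chained connector only.
        """
        ids = [endpoint_ids[0]]
        for p in points[1:-1]:
            ids.append(self.add_anchor(p))
        ids.append(endpoint_ids[1])
        created: list[int] = []
        n_segments = len(ids) - 1
        for i in range(n_segments):
            cid = self.take_id()
            self.connectors.append(
                ConnectorSpec(
                    id=cid,
                    name=f"{name}-{i}",
                    from_id=ids[i],
                    to_id=ids[i + 1],
                    head_end=head_end if i == 0 else "none",
                    tail_end=tail_end if i == n_segments - 1 else "none",
                )
            )
            created.append(cid)
        return created


def build_shape_graph(
    diagram: Diagram,
    profile: ColorProfile,
    endpoint_tolerance: float = DEFAULT_ENDPOINT_TOLERANCE,
) -> AnchoredShapeGraph:
    """Convert a diagram into export-ready shapes, connectors and groups.

    Every node glyph becomes one autoshape, every reaction gets a small
    reaction-centre shape, and each polyline (backbone and participant
    connectors) with ``k`` interior bends contributes ``k`` invisible anchors
    and ``k + 1`` chained connectors, all attached by shape-id reference.
    Catalysis/activation circles and inhibition bars become decoration
    shapes grouped with their adjacent connector segment.
    """
    violations = validate_diagram(diagram, endpoint_tolerance)
    if violations:
        raise PptxExportError("invalid diagram: " + "; ".join(violations))

    b = _Builder(diagram, profile, endpoint_tolerance)

    for node in diagram.nodes:
        sid = b.take_id()
        b.node_shape[node.id] = sid
        b.shapes.append(
            ShapeSpec(
                id=sid,
                name=node.id,
                kind="node",
                rect=node.bounds,
                geometry=_GEOMETRY_BY_CLASS[node.schema_class],
                fill=profile.node_fill[node.schema_class],
                stroke=profile.node_stroke[node.schema_class],
                text=node.display_name,
            )
        )

    for edge in diagram.edges:
        center_id = b.take_id()
        rx, ry = edge.reaction_point
        b.shapes.append(
            ShapeSpec(
                id=center_id,
                name=edge.id,
                kind="center",
                rect=Rect(rx - CENTER_SIZE / 2, ry - CENTER_SIZE / 2,
                          CENTER_SIZE, CENTER_SIZE),
                geometry="rect",
                fill="#FFFFFF",
                stroke="#404040",
            )
        )

        if len(edge.segments) >= 2:
            start = b.resolve_endpoint(edge.segments[0], edge, center_id)
            end = b.resolve_endpoint(edge.segments[-1], edge, center_id)
            b.chain((start, end), edge.segments, f"{edge.id}-backbone")

        for ci, conn in enumerate(edge.connectors):
            if len(conn.points) < 2:
                continue
            start = b.node_shape[conn.node_id]
            # all participant polylines chain toward the reaction centre
            head = "triangle" if conn.ending is LineEnding.ARROW else "none"
            created = b.chain(
                (start, center_id),
                conn.points,
                f"{edge.id}-{conn.role.value}{ci}",
                head_end=head,
            )
            if conn.ending in (LineEnding.CIRCLE, LineEnding.BAR):
                deco_id = b.take_id()
                end_pt = conn.points[-1]
                ref_pt = conn.points[-2]
                if conn.ending is LineEnding.CIRCLE:
                    rect = Rect(end_pt[0] - 4, end_pt[1] - 4, 8, 8)
                    geom = "ellipse"
                    fill = "#FFFFFF"
                else:
                    horizontal = abs(end_pt[0] - ref_pt[0]) >= abs(end_pt[1] - ref_pt[1])
                    rect = (
                        Rect(end_pt[0] - 1, end_pt[1] - 5, 2, 10)
                        if horizontal
                        else Rect(end_pt[0] - 5, end_pt[1] - 1, 10, 2)
                    )
                    geom = "rect"
                    fill = "#404040"
                b.shapes.append(
                    ShapeSpec(
                        id=deco_id,
                        name=f"{edge.id}-{conn.role.value}{ci}-ending",
                        kind="decoration",
                        rect=rect,
                        geometry=geom,
                        fill=fill,
                        stroke="#404040",
                    )
                )
                b.groups.append(frozenset({deco_id, created[-1]}))

    return AnchoredShapeGraph(
        canvas=diagram.canvas,
        shapes=tuple(b.shapes),
        connectors=tuple(b.connectors),
        groups=tuple(b.groups),
    )


# ---------------------------------------------------------------------------
# OOXML serialization

def _emu(v: float) -> int:
    return int(round(v * EMU_PER_UNIT))


def _hex6(color: str) -> str:
    r, g, b, _ = parse_color(color)
    return f"{r:02X}{g:02X}{b:02X}"


def _sub(parent, ns: str, tag: str, **attrs) -> etree._Element:
    el = etree.SubElement(parent, f"{{{ns}}}{tag}")
    for k, v in attrs.items():
        el.set(k, str(v))
    return el


def _shape_xml(parent, shape: ShapeSpec, origin: Point) -> None:
    sp = _sub(parent, NS_P, "sp")
    nv = _sub(sp, NS_P, "nvSpPr")
    _sub(nv, NS_P, "cNvPr", id=shape.id, name=shape.name)
    _sub(nv, NS_P, "cNvSpPr")
    _sub(nv, NS_P, "nvPr")
    sppr = _sub(sp, NS_P, "spPr")
    xfrm = _sub(sppr, NS_A, "xfrm")
    _sub(xfrm, NS_A, "off", x=_emu(shape.rect.x - origin[0]), y=_emu(shape.rect.y - origin[1]))
    _sub(xfrm, NS_A, "ext", cx=max(1, _emu(shape.rect.w)), cy=max(1, _emu(shape.rect.h)))
    geom = _sub(sppr, NS_A, "prstGeom", prst=shape.geometry)
    _sub(geom, NS_A, "avLst")
    if shape.fill is None:
        _sub(sppr, NS_A, "noFill")
    else:
        fill = _sub(sppr, NS_A, "solidFill")
        _sub(fill, NS_A, "srgbClr", val=_hex6(shape.fill))
    ln = _sub(sppr, NS_A, "ln", w=12700)
    if shape.stroke is None:
        _sub(ln, NS_A, "noFill")
    else:
        lnfill = _sub(ln, NS_A, "solidFill")
        _sub(lnfill, NS_A, "srgbClr", val=_hex6(shape.stroke))
    if shape.text:
        tx = _sub(sp, NS_P, "txBody")
        _sub(tx, NS_A, "bodyPr", wrap="square", anchor="ctr")
        _sub(tx, NS_A, "lstStyle")
        para = _sub(tx, NS_A, "p")
        ppr = _sub(para, NS_A, "pPr", algn="ctr")
        run = _sub(para, NS_A, "r")
        _sub(run, NS_A, "rPr", lang="en-US", sz=900)
        t = _sub(run, NS_A, "t")
        t.text = shape.text


def _side_midpoints(r: Rect) -> list[Point]:
    cx, cy = r.center
    # connection-site order of preset rectangles: top, left, bottom, right
    return [(cx, r.y), (r.x, cy), (cx, r.bottom), (r.right, cy)]


def _nearest_site(r: Rect, toward: Point) -> int:
    sites = _side_midpoints(r)
    return min(range(4), key=lambda i: _dist(sites[i], toward))


def _connector_xml(
    parent, conn: ConnectorSpec, shapes: dict[int, ShapeSpec], origin: Point
) -> None:
    a = shapes[conn.from_id]
    bshape = shapes[conn.to_id]
    st_idx = _nearest_site(a.rect, bshape.rect.center)
    end_idx = _nearest_site(bshape.rect, a.rect.center)
    p1 = _side_midpoints(a.rect)[st_idx]
    p2 = _side_midpoints(bshape.rect)[end_idx]

    cxn = _sub(parent, NS_P, "cxnSp")
    nv = _sub(cxn, NS_P, "nvCxnSpPr")
    _sub(nv, NS_P, "cNvPr", id=conn.id, name=conn.name)
    cnv = _sub(nv, NS_P, "cNvCxnSpPr")
    _sub(cnv, NS_A, "stCxn", id=conn.from_id, idx=st_idx)
    _sub(cnv, NS_A, "endCxn", id=conn.to_id, idx=end_idx)
    _sub(nv, NS_P, "nvPr")
    sppr = _sub(cxn, NS_P, "spPr")
    # frame only; the true endpoints derive from the referenced shapes
    x0, y0 = min(p1[0], p2[0]) - origin[0], min(p1[1], p2[1]) - origin[1]
    xfrm = _sub(
        sppr, NS_A, "xfrm",
        **({"flipH": "1"} if p2[0] < p1[0] else {}),
        **({"flipV": "1"} if p2[1] < p1[1] else {}),
    )
    _sub(xfrm, NS_A, "off", x=_emu(x0), y=_emu(y0))
    _sub(xfrm, NS_A, "ext", cx=max(1, _emu(abs(p2[0] - p1[0]))),
         cy=max(1, _emu(abs(p2[1] - p1[1]))))
    geom = _sub(sppr, NS_A, "prstGeom", prst="straightConnector1")
    _sub(geom, NS_A, "avLst")
    ln = _sub(sppr, NS_A, "ln", w=12700)
    fill = _sub(ln, NS_A, "solidFill")
    _sub(fill, NS_A, "srgbClr", val=_hex6(conn.stroke))
    if conn.dashed:
        _sub(ln, NS_A, "prstDash", val="dash")
    _sub(ln, NS_A, "headEnd", type=conn.head_end)
    _sub(ln, NS_A, "tailEnd", type=conn.tail_end)


def _slide_xml(graph: AnchoredShapeGraph, group_id_start: int) -> bytes:
    nsmap = {"a": NS_A, "r": NS_R, "p": NS_P}
    sld = etree.Element(f"{{{NS_P}}}sld", nsmap=nsmap)
    csld = _sub(sld, NS_P, "cSld")
    tree = _sub(csld, NS_P, "spTree")
    nv = _sub(tree, NS_P, "nvGrpSpPr")
    _sub(nv, NS_P, "cNvPr", id=1, name="Diagram")
    _sub(nv, NS_P, "cNvGrpSpPr")
    _sub(nv, NS_P, "nvPr")
    gpr = _sub(tree, NS_P, "grpSpPr")
    xfrm = _sub(gpr, NS_A, "xfrm")
    _sub(xfrm, NS_A, "off", x=0, y=0)
    _sub(xfrm, NS_A, "ext", cx=_emu(graph.canvas.w), cy=_emu(graph.canvas.h))
    _sub(xfrm, NS_A, "chOff", x=0, y=0)
    _sub(xfrm, NS_A, "chExt", cx=_emu(graph.canvas.w), cy=_emu(graph.canvas.h))

    origin = (graph.canvas.x, graph.canvas.y)
    shapes = graph.shape_by_id()
    grouped: set[int] = set().union(*graph.groups) if graph.groups else set()

    for shape in graph.shapes:
        if shape.id not in grouped:
            _shape_xml(tree, shape, origin)
    for conn in graph.connectors:
        if conn.id not in grouped:
            _connector_xml(tree, conn, shapes, origin)

    gid = group_id_start
    for group in graph.groups:
        member_shapes = [shapes[m] for m in group if m in shapes]
        member_conns = [c for c in graph.connectors if c.id in group]
        rects = [s.rect for s in member_shapes]
        for c in member_conns:
            rects.append(shapes[c.from_id].rect)
            rects.append(shapes[c.to_id].rect)
        x = min(r.x for r in rects)
        y = min(r.y for r in rects)
        w = max(r.right for r in rects) - x
        h = max(r.bottom for r in rects) - y
        grp = _sub(tree, NS_P, "grpSp")
        gnv = _sub(grp, NS_P, "nvGrpSpPr")
        _sub(gnv, NS_P, "cNvPr", id=gid, name=f"ending-group-{gid}")
        gid += 1
        _sub(gnv, NS_P, "cNvGrpSpPr")
        _sub(gnv, NS_P, "nvPr")
        ggpr = _sub(grp, NS_P, "grpSpPr")
        gx = _sub(ggpr, NS_A, "xfrm")
        _sub(gx, NS_A, "off", x=_emu(x - origin[0]), y=_emu(y - origin[1]))
        _sub(gx, NS_A, "ext", cx=max(1, _emu(w)), cy=max(1, _emu(h)))
        _sub(gx, NS_A, "chOff", x=_emu(x - origin[0]), y=_emu(y - origin[1]))
        _sub(gx, NS_A, "chExt", cx=max(1, _emu(w)), cy=max(1, _emu(h)))
        for s in sorted(member_shapes, key=lambda s: s.id):
            _shape_xml(grp, s, origin)
        for c in sorted(member_conns, key=lambda c: c.id):
            _connector_xml(grp, c, shapes, origin)

    clr = _sub(sld, NS_P, "clrMapOvr")
    _sub(clr, NS_A, "masterClrMapping")
    return etree.tostring(sld, xml_declaration=True, encoding="UTF-8",
                          standalone=True)


_CONTENT_TYPES = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Types xmlns="{NS_CT}">
<Default Extension="rels" ContentType="application/vnd.openxmlformats-package.relationships+xml"/>
<Default Extension="xml" ContentType="application/xml"/>
<Override PartName="/ppt/presentation.xml" ContentType="application/vnd.openxmlformats-officedocument.presentationml.presentation.main+xml"/>
<Override PartName="/ppt/slideMasters/slideMaster1.xml" ContentType="application/vnd.openxmlformats-officedocument.presentationml.slideMaster+xml"/>
<Override PartName="/ppt/slideLayouts/slideLayout1.xml" ContentType="application/vnd.openxmlformats-officedocument.presentationml.slideLayout+xml"/>
<Override PartName="/ppt/slides/slide1.xml" ContentType="application/vnd.openxmlformats-officedocument.presentationml.slide+xml"/>
<Override PartName="/ppt/theme/theme1.xml" ContentType="application/vnd.openxmlformats-officedocument.theme+xml"/>
</Types>
"""

_ROOT_RELS = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="{NS_REL}">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/officeDocument" Target="ppt/presentation.xml"/>
</Relationships>
"""

_PRES_RELS = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="{NS_REL}">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/slideMaster" Target="slideMasters/slideMaster1.xml"/>
<Relationship Id="rId2" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/slide" Target="slides/slide1.xml"/>
</Relationships>
"""

_SLIDE_RELS = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="{NS_REL}">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/slideLayout" Target="../slideLayouts/slideLayout1.xml"/>
</Relationships>
"""

_LAYOUT_RELS = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="{NS_REL}">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/slideMaster" Target="../slideMasters/slideMaster1.xml"/>
</Relationships>
"""

_MASTER_RELS = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="{NS_REL}">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/slideLayout" Target="../slideLayouts/slideLayout1.xml"/>
<Relationship Id="rId2" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/theme" Target="../theme/theme1.xml"/>
</Relationships>
"""

_EMPTY_SPTREE = (
    '<p:cSld><p:spTree><p:nvGrpSpPr><p:cNvPr id="1" name=""/>'
    "<p:cNvGrpSpPr/><p:nvPr/></p:nvGrpSpPr><p:grpSpPr/></p:spTree></p:cSld>"
)

_MASTER = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<p:sldMaster xmlns:a="{NS_A}" xmlns:r="{NS_R}" xmlns:p="{NS_P}">
{_EMPTY_SPTREE}
<p:clrMap bg1="lt1" tx1="dk1" bg2="lt2" tx2="dk2" accent1="accent1" accent2="accent2" accent3="accent3" accent4="accent4" accent5="accent5" accent6="accent6" hlink="hlink" folHlink="folHlink"/>
<p:sldLayoutIdLst><p:sldLayoutId id="2147483649" r:id="rId1"/></p:sldLayoutIdLst>
</p:sldMaster>
"""

_LAYOUT = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<p:sldLayout xmlns:a="{NS_A}" xmlns:r="{NS_R}" xmlns:p="{NS_P}" type="blank">
{_EMPTY_SPTREE}
<p:clrMapOvr><a:masterClrMapping/></p:clrMapOvr>
</p:sldLayout>
"""

_FMT_FILL = (
    '<a:solidFill><a:schemeClr val="phClr"/></a:solidFill>'
)

_THEME = f"""<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<a:theme xmlns:a="{NS_A}" name="pathviz">
<a:themeElements>
<a:clrScheme name="pathviz">
<a:dk1><a:srgbClr val="000000"/></a:dk1><a:lt1><a:srgbClr val="FFFFFF"/></a:lt1>
<a:dk2><a:srgbClr val="44546A"/></a:dk2><a:lt2><a:srgbClr val="E7E6E6"/></a:lt2>
<a:accent1><a:srgbClr val="4472C4"/></a:accent1><a:accent2><a:srgbClr val="ED7D31"/></a:accent2>
<a:accent3><a:srgbClr val="A5A5A5"/></a:accent3><a:accent4><a:srgbClr val="FFC000"/></a:accent4>
<a:accent5><a:srgbClr val="5B9BD5"/></a:accent5><a:accent6><a:srgbClr val="70AD47"/></a:accent6>
<a:hlink><a:srgbClr val="0563C1"/></a:hlink><a:folHlink><a:srgbClr val="954F72"/></a:folHlink>
</a:clrScheme>
<a:fontScheme name="pathviz">
<a:majorFont><a:latin typeface="Calibri"/><a:ea typeface=""/><a:cs typeface=""/></a:majorFont>
<a:minorFont><a:latin typeface="Calibri"/><a:ea typeface=""/><a:cs typeface=""/></a:minorFont>
</a:fontScheme>
<a:fmtScheme name="pathviz">
<a:fillStyleLst>{_FMT_FILL}{_FMT_FILL}{_FMT_FILL}</a:fillStyleLst>
<a:lnStyleLst>
<a:ln w="6350">{_FMT_FILL}</a:ln><a:ln w="12700">{_FMT_FILL}</a:ln><a:ln w="19050">{_FMT_FILL}</a:ln>
</a:lnStyleLst>
<a:effectStyleLst><a:effectStyle><a:effectLst/></a:effectStyle><a:effectStyle><a:effectLst/></a:effectStyle><a:effectStyle><a:effectLst/></a:effectStyle></a:effectStyleLst>
<a:bgFillStyleLst>{_FMT_FILL}{_FMT_FILL}{_FMT_FILL}</a:bgFillStyleLst>
</a:fmtScheme>
</a:themeElements>
</a:theme>
"""


def _presentation_xml(slide_cx: int, slide_cy: int) -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8" standalone="yes"?>\n'
        f'<p:presentation xmlns:a="{NS_A}" xmlns:r="{NS_R}" xmlns:p="{NS_P}">'
        '<p:sldMasterIdLst><p:sldMasterId id="2147483648" r:id="rId1"/></p:sldMasterIdLst>'
        '<p:sldIdLst><p:sldId id="256" r:id="rId2"/></p:sldIdLst>'
        f'<p:sldSz cx="{slide_cx}" cy="{slide_cy}"/>'
        '<p:notesSz cx="6858000" cy="9144000"/>'
        "</p:presentation>\n"
    )


def write_pptx(
    graph: AnchoredShapeGraph,
    path: str,
    slide_size: Optional[tuple[float, float]] = None,
) -> None:
    """Write the shape graph as a single-slide PresentationML package.

    ``slide_size`` is in canvas units and defaults to the diagram canvas.
    The archive uses fixed entry timestamps, so identical graphs yield
    byte-identical files.
    """
    if slide_size is None:
        slide_size = (graph.canvas.w, graph.canvas.h)
    max_shape_id = max(
        [s.id for s in graph.shapes] + [c.id for c in graph.connectors], default=1
    )
    slide = _slide_xml(graph, group_id_start=max_shape_id + 1)
    parts: list[tuple[str, bytes]] = [
        ("[Content_Types].xml", _CONTENT_TYPES.encode()),
        ("_rels/.rels", _ROOT_RELS.encode()),
        ("ppt/presentation.xml",
         _presentation_xml(_emu(slide_size[0]), _emu(slide_size[1])).encode()),
        ("ppt/_rels/presentation.xml.rels", _PRES_RELS.encode()),
        ("ppt/slides/slide1.xml", slide),
        ("ppt/slides/_rels/slide1.xml.rels", _SLIDE_RELS.encode()),
        ("ppt/slideLayouts/slideLayout1.xml", _LAYOUT.encode()),
        ("ppt/slideLayouts/_rels/slideLayout1.xml.rels", _LAYOUT_RELS.encode()),
        ("ppt/slideMasters/slideMaster1.xml", _MASTER.encode()),
        ("ppt/slideMasters/_rels/slideMaster1.xml.rels", _MASTER_RELS.encode()),
        ("ppt/theme/theme1.xml", _THEME.encode()),
    ]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, data in parts:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, data)


# ---------------------------------------------------------------------------
# Verification

_REQUIRED_PARTS = (
    "[Content_Types].xml",
    "_rels/.rels",
    "ppt/presentation.xml",
    "ppt/slides/slide1.xml",
    "ppt/slideLayouts/slideLayout1.xml",
    "ppt/slideMasters/slideMaster1.xml",
    "ppt/theme/theme1.xml",
)


@dataclass
class ExportReport:
    missing_parts: list[str] = field(default_factory=list)
    unresolved_relationships: list[str] = field(default_factory=list)
    dangling_refs: int = 0
    unattached_connectors: int = 0
    out_of_bounds: int = 0
    shape_count: int = 0
    connector_count: int = 0
    anchor_count: int = 0
    group_count: int = 0

    @property
    def ok(self) -> bool:
        return (
            not self.missing_parts
            and not self.unresolved_relationships
            and self.dangling_refs == 0
            and self.unattached_connectors == 0
            and self.out_of_bounds == 0
        )


def _resolve_rel_target(base_dir: str, target: str) -> str:
    parts = (base_dir.split("/") if base_dir else []) + target.split("/")
    out: list[str] = []
    for p in parts:
        if p == "..":
            if out:
                out.pop()
        elif p not in (".", ""):
            out.append(p)
    return "/".join(out)


def verify_export(path: str) -> ExportReport:
    """Structural validation of an exported package.

    Checks that the required package parts exist, that every relationship
    target resolves, that every connector carries both connection references
    and that those references point at shapes present on the slide, and that
    no shape lies outside the slide bounds.
    """
    report = ExportReport()
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, OSError) as exc:
        raise PptxExportError(f"unreadable export: {exc}") from exc
    with zf:
        names = set(zf.namelist())
        for part in _REQUIRED_PARTS:
            if part not in names:
                report.missing_parts.append(part)
        if report.missing_parts:
            return report

        for name in sorted(names):
            if not name.endswith(".rels"):
                continue
            rel_root = etree.fromstring(zf.read(name))
            base_dir = name.rsplit("_rels/", 1)[0].rstrip("/")
            for rel in rel_root:
                target = rel.get("Target", "")
                if rel.get("TargetMode") == "External":
                    continue
                resolved = _resolve_rel_target(base_dir, target)
                if resolved not in names:
                    report.unresolved_relationships.append(f"{name} -> {target}")

        pres = etree.fromstring(zf.read("ppt/presentation.xml"))
        sldsz = pres.find(f"{{{NS_P}}}sldSz")
        slide_cx = int(sldsz.get("cx"))
        slide_cy = int(sldsz.get("cy"))

        slide = etree.fromstring(zf.read("ppt/slides/slide1.xml"))
        shape_ids: set[int] = set()
        for sp in slide.iter(f"{{{NS_P}}}sp"):
            cnv = sp.find(f"{{{NS_P}}}nvSpPr/{{{NS_P}}}cNvPr")
            if cnv is not None:
                shape_ids.add(int(cnv.get("id")))
                report.shape_count += 1
                nofill = sp.find(f"{{{NS_P}}}spPr/{{{NS_A}}}noFill")
                noline = sp.find(f"{{{NS_P}}}spPr/{{{NS_A}}}ln/{{{NS_A}}}noFill")
                if nofill is not None and noline is not None:
                    report.anchor_count += 1
            xfrm = sp.find(f"{{{NS_P}}}spPr/{{{NS_A}}}xfrm")
            if xfrm is not None:
                off = xfrm.find(f"{{{NS_A}}}off")
                ext = xfrm.find(f"{{{NS_A}}}ext")
                x, y = int(off.get("x")), int(off.get("y"))
                cx, cy = int(ext.get("cx")), int(ext.get("cy"))
                if x < 0 or y < 0 or x + cx > slide_cx or y + cy > slide_cy:
                    report.out_of_bounds += 1

        report.group_count = sum(1 for _ in slide.iter(f"{{{NS_P}}}grpSp"))

        for cxn in slide.iter(f"{{{NS_P}}}cxnSp"):
            report.connector_count += 1
            cnvc = cxn.find(f"{{{NS_P}}}nvCxnSpPr/{{{NS_P}}}cNvCxnSpPr")
            st = cnvc.find(f"{{{NS_A}}}stCxn") if cnvc is not None else None
            en = cnvc.find(f"{{{NS_A}}}endCxn") if cnvc is not None else None
            if st is None or en is None:
                report.unattached_connectors += 1
                continue
            for ref in (st, en):
                if int(ref.get("id")) not in shape_ids:
                    report.dangling_refs += 1
    return report
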