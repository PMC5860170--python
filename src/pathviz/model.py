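"""Core geometric and hierarchical data types for pathway diagrams.

The coordinate convention follows SVG: the origin is the top-left corner of
the canvas, y grows downward, and one canvas unit renders as one CSS pixel at
zoom 1.  Rectangles are stored as ``(x, y, w, h)`` with closed edges
(``x .. x + w`` inclusive) so that containment tests at glyph boundaries
behave predictably.

A :class:`Diagram` is the in-memory form of a classic lower-level pathway
diagram: molecular glyphs (:class:`NodeGlyph`), segmented reaction edges
(:class:`ReactionEdge`) whose participant connectors carry SBGN-style line
endings, and cellular compartments.  Higher-level organisation lives in
:class:`PathwayHierarchy`, and :class:`SubpathwayAssignment` records which
reactions of a parent diagram belong to which subpathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Sequence

Point = tuple[float, float]

#: Tolerance (canvas units) within which a connector polyline must terminate
#: on its reaction backbone or reaction point.
DEFAULT_ENDPOINT_TOLERANCE = 0.5


class SchemaClass(str, Enum):
    """Minimal subset of SBGN process-description glyph classes."""

    PROTEIN = "protein"
    CHEMICAL = "chemical"
    COMPLEX = "complex"
    ENTITY_SET = "entity_set"
    GENE = "gene"
    RNA = "rna"
    PROCESS_NODE = "process_node"


class ConnectorRole(str, Enum):
    INPUT = "input"
    OUTPUT = "output"
    CATALYST = "catalyst"
    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"


class LineEnding(str, Enum):
    NONE = "none"
    ARROW = "arrow"
    CIRCLE = "circle"
    BAR = "bar"


#: Line endings permitted for each connector role (SBGN conventions: products
#: get arrows, catalysis/activation circles, inhibition a bar).
ALLOWED_ENDINGS: dict[ConnectorRole, frozenset[LineEnding]] = {
    ConnectorRole.INPUT: frozenset({LineEnding.NONE}),
    ConnectorRole.OUTPUT: frozenset({LineEnding.NONE, LineEnding.ARROW}),
    ConnectorRole.CATALYST: frozenset({LineEnding.NONE, LineEnding.CIRCLE}),
    ConnectorRole.ACTIVATOR: frozenset({LineEnding.NONE, LineEnding.CIRCLE}),
    ConnectorRole.INHIBITOR: frozenset({LineEnding.NONE, LineEnding.BAR}),
}


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in canvas units.

    Degenerate (zero width or height) rectangles are representable — overlay
    hit bars legitimately have width 0 when nothing was found — but diagram
    validation requires strictly positive extents for glyphs and canvases.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError(f"non-finite rectangle coordinate: {v!r}")
        if self.w < 0 or self.h < 0:
            raise ValueError(f"negative rectangle extent: w={self.w}, h={self.h}")

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> Point:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def contains_point(self, p: Point) -> bool:
        """Closed-interval containment (edges count as inside)."""
        return self.x <= p[0] <= self.right and self.y <= p[1] <= self.bottom

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.right <= self.right
            and other.bottom <= self.bottom
        )

    def intersects_interior(self, other: "Rect") -> bool:
        """True when the open interiors overlap (shared edges do not count)."""
        return (
            self.x < other.right
            and other.x < self.right
            and self.y < other.bottom
            and other.y < self.bottom
        )

    def intersect(self, other: "Rect") -> Optional["Rect"]:
        x = max(self.x, other.x)
        y = max(self.y, other.y)
        r = min(self.right, other.right)
        b = min(self.bottom, other.bottom)
        if r <= x or b <= y:
            return None
        return Rect(x, y, r - x, b - y)

    def padded(self, pad: float) -> "Rect":
        """Grow (or shrink, for negative pad) by ``pad`` on every side."""
        if 2 * pad + self.w < 0 or 2 * pad + self.h < 0:
            raise ValueError("padding collapses rectangle")
        return Rect(self.x - pad, self.y - pad, self.w + 2 * pad, self.h + 2 * pad)


def rect_union(rects: Sequence[Rect]) -> Rect:
    """Smallest rectangle containing every input rectangle."""
    if not rects:
        raise ValueError("empty union")
    x = min(r.x for r in rects)
    y = min(r.y for r in rects)
    right = max(r.right for r in rects)
    bottom = max(r.bottom for r in rects)
    return Rect(x, y, right - x, bottom - y)


def points_bbox(points: Sequence[Point]) -> Rect:
    """Bounding rectangle of a point set (may be degenerate)."""
    if not points:
        raise ValueError("empty point set")
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return Rect(min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))


@dataclass(frozen=True)
class NodeGlyph:
    id: str
    schema_class: SchemaClass
    display_name: str
    bounds: Rect
    compartment_id: Optional[str] = None


@dataclass(frozen=True)
class Connector:
    """Polyline joining a participant glyph to its reaction.

    Points are ordered from the node toward the reaction centre; the last
    point must terminate on the reaction backbone or reaction point (within
    the diagram's endpoint tolerance).
    """

    role: ConnectorRole
    node_id: str
    points: tuple[Point, ...]
    ending: LineEnding = LineEnding.NONE

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("connector needs at least one point")


@dataclass(frozen=True)
class ReactionEdge:
    id: str
    reaction_point: Point
    segments: tuple[Point, ...]
    connectors: tuple[Connector, ...]

    def all_points(self) -> list[Point]:
        pts: list[Point] = [self.reaction_point]
        pts.extend(self.segments)
        for c in self.connectors:
            pts.extend(c.points)
        return pts


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str
    outer: Rect
    inner: Optional[Rect] = None


@dataclass(frozen=True)
class Diagram:
    pathway_id: str
    canvas: Rect
    nodes: tuple[NodeGlyph, ...]
    edges: tuple[ReactionEdge, ...]
    compartments: tuple[Compartment, ...] = ()

    def node_by_id(self) -> dict[str, NodeGlyph]:
        return {n.id: n for n in self.nodes}

    def edge_by_id(self) -> dict[str, ReactionEdge]:
        return {e.id: e for e in self.edges}


class HierarchyKind(str, Enum):
    HIGHER_LEVEL = "higher_level"
    LOWER_LEVEL = "lower_level"


@dataclass
class PathwayEntry:
    stable_id: str
    name: str
    kind: HierarchyKind
    children: list["PathwayEntry"] = field(default_factory=list)


@dataclass
class PathwayHierarchy:
    root: PathwayEntry

    def walk(self) -> Iterator[PathwayEntry]:
        stack = [self.root]
        while stack:
            entry = stack.pop()
            yield entry
            stack.extend(reversed(entry.children))

    def depth(self) -> int:
        def _d(e: PathwayEntry) -> int:
            return 1 + max((_d(c) for c in e.children), default=0)

        return _d(self.root)


@dataclass(frozen=True)
class SubpathwayAssignment:
    """Which reactions of a parent diagram belong to which subpathway."""

    parent_pathway_id: str
    groups: dict[str, frozenset[str]]
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "groups", {k: frozenset(v) for k, v in self.groups.items()}
        )


def _point_segment_distance(p: Point, a: Point, b: Point) -> float:
    ax, ay = a
    bx, by = b
    px, py = p
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0.0:
        return math.hypot(px - ax, py - ay)
    t = max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / L2))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def _point_polyline_distance(p: Point, polyline: Sequence[Point]) -> float:
    if len(polyline) == 1:
        return math.hypot(p[0] - polyline[0][0], p[1] - polyline[0][1])
    return min(
        _point_segment_distance(p, polyline[i], polyline[i + 1])
        for i in range(len(polyline) - 1)
    )


def validate_diagram(
    diagram: Diagram, endpoint_tolerance: float = DEFAULT_ENDPOINT_TOLERANCE
) -> list[str]:
    """Check every structural invariant of a diagram.

    Returns a list of human-readable violations, each naming the offending
    element; an empty list means the diagram is well-formed.  Violations are
    data, not exceptions, so callers can report them all at once.
    """
    violations: list[str] = []
    canvas = diagram.canvas
    if canvas.w <= 0 or canvas.h <= 0:
        violations.append(f"canvas of '{diagram.pathway_id}' has non-positive extent")

    node_ids: set[str] = set()
    compartment_ids = {c.id for c in diagram.compartments}
    for node in diagram.nodes:
        if node.id in node_ids:
            violations.append(f"duplicate node id '{node.id}'")
        node_ids.add(node.id)
        if node.bounds.w <= 0 or node.bounds.h <= 0:
            violations.append(f"node '{node.id}' has non-positive bounds")
        if not canvas.contains_rect(node.bounds):
            violations.append(f"node '{node.id}' bounds outside canvas")
        if node.compartment_id is not None and node.compartment_id not in compartment_ids:
            violations.append(
                f"node '{node.id}' references unknown compartment "
                f"'{node.compartment_id}'"
            )

    seen_edge_ids: set[str] = set()
    for edge in diagram.edges:
        if edge.id in seen_edge_ids or edge.id in node_ids:
            violations.append(f"duplicate edge id '{edge.id}'")
        seen_edge_ids.add(edge.id)
        for p in edge.all_points():
            if not canvas.contains_point(p):
                violations.append(f"edge '{edge.id}' point {p} outside canvas")
                break
        roles = [c.role for c in edge.connectors]
        if ConnectorRole.INPUT not in roles:
            violations.append(f"edge '{edge.id}' has no input connector")
        if ConnectorRole.OUTPUT not in roles:
            violations.append(f"edge '{edge.id}' has no output connector")
        backbone = list(edge.segments) or [edge.reaction_point]
        for c in edge.connectors:
            if c.node_id not in node_ids:
                violations.append(
                    f"edge '{edge.id}' connector references unknown node '{c.node_id}'"
                )
            if c.ending not in ALLOWED_ENDINGS[c.role]:
                violations.append(
                    f"edge '{edge.id}' connector to '{c.node_id}': ending "
                    f"'{c.ending.value}' not allowed for role '{c.role.value}'"
                )
            terminal = c.points[-1]
            d = min(
                _point_polyline_distance(terminal, backbone),
                math.hypot(
                    terminal[0] - edge.reaction_point[0],
                    terminal[1] - edge.reaction_point[1],
                ),
            )
            if d > endpoint_tolerance:
                violations.append(
                    f"edge '{edge.id}' connector to '{c.node_id}' terminates "
                    f"{d:.2f} units away from backbone (tolerance {endpoint_tolerance})"
                )

    for comp in diagram.compartments:
        if comp.inner is not None:
            inside = (
                comp.outer.x < comp.inner.x
                and comp.outer.y < comp.inner.y
                and comp.inner.right < comp.outer.right
                and comp.inner.bottom < comp.outer.bottom
            )
            if not inside:
                violations.append(
                    f"compartment '{comp.id}' inner rect not strictly inside outer"
                )
        if not canvas.contains_rect(comp.outer):
            violations.append(f"compartment '{comp.id}' outside canvas")

    return violations


def validate_assignment(
    diagram: Diagram, assignment: SubpathwayAssignment
) -> list[str]:
    """Check a subpathway assignment against its parent diagram."""
    violations: list[str] = []
    edge_ids = {e.id for e in diagram.edges}
    seen: dict[str, str] = {}
    for sp_id, members in assignment.groups.items():
        if not members:
            violations.append(f"subpathway '{sp_id}' has no reactions")
        for rid in members:
            if rid not in edge_ids:
                violations.append(
                    f"subpathway '{sp_id}' references unknown reaction '{rid}'"
                )
            elif rid in seen:
                violations.append(
                    f"reaction '{rid}' assigned to both '{seen[rid]}' and '{sp_id}'"
                )
            else:
                seen[rid] = sp_id
    return violations
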