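"""Deterministic synthetic fixtures for every input the toolkit consumes.

The generators emulate the shapes of real pathway data — grid-laid diagrams
with segmented reactions, annotated EHLD SVGs, hierarchies, pathway entity
sets with a planted enriched pathway — without any biological content.  All
of them are pure functions of a :class:`FixtureSpec`: the same spec always
produces byte-identical files, which is exactly the persistence contract the
release-time highlight precomputation must satisfy.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .io import DiagramDocument, write_diagram, write_hierarchy
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
)
from .overlay import PathwayEntitySets, write_gmt

SVG_NS = "http://www.w3.org/2000/svg"

NODE_W = 70.0
NODE_H = 36.0
CELL_W = 95.0
CELL_H = 70.0
MARGIN = 24.0


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study fixture (all generators seeded)."""

    seed: int = 0
    n_nodes: int = 12
    n_reactions: int = 6
    n_subpathways: int = 3
    n_compartments: int = 1
    canvas: Rect = field(default_factory=lambda: Rect(0, 0, 1000, 700))
    ehld_regions: int = 5
    universe_size: int = 200
    n_pathway_sets: int = 10
    set_size: int = 20
    query_size: int = 20
    hit_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_nodes", "n_reactions", "n_subpathways",
                     "n_compartments", "ehld_regions"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        if not (0.0 <= self.hit_fraction <= 1.0):
            raise FixtureError("hit_fraction must lie in [0, 1]")


def _round2(v: float) -> float:
    return round(float(v), 2)


def _boundary_point(bounds: Rect, toward: Point) -> Point:
    """Side midpoint of a glyph nearest the target point."""
    cx, cy = bounds.center
    sides = [
        (cx, bounds.y),
        (bounds.x, cy),
        (cx, bounds.bottom),
        (bounds.right, cy),
    ]
    return min(sides, key=lambda s: math.hypot(s[0] - toward[0], s[1] - toward[1]))


def generate_diagram(spec: FixtureSpec) -> DiagramDocument:
    """Grid-laid synthetic diagram with a contiguous subpathway partition.

    Nodes sit on a jittered grid without overlap; each reaction joins an
    input glyph to its nearest free neighbour through a backbone with 0–2
    bends ending at the reaction point, with optional catalyst and inhibitor
    participants.  Subpathways partition the reactions into spatially
    contiguous clusters (chunks of the x-sorted reaction list).
    """
    rng = np.random.default_rng(spec.seed)
    canvas = spec.canvas
    if spec.n_nodes < 2 and spec.n_reactions > 0:
        raise FixtureError("need at least two nodes for reactions")

    cols = int((canvas.w - 2 * MARGIN) // CELL_W)
    rows = int((canvas.h - 2 * MARGIN) // CELL_H)
    if cols * rows < spec.n_nodes:
        raise FixtureError(
            f"overcrowded fixture: {spec.n_nodes} nodes do not fit a "
            f"{cols}x{rows} grid on this canvas"
        )

    compartments: list[Compartment] = []
    if spec.n_compartments > 0:
        comp_w = (canvas.w - 2 * MARGIN) / spec.n_compartments
        for i in range(spec.n_compartments):
            outer = Rect(
                _round2(canvas.x + MARGIN + i * comp_w + 4),
                _round2(canvas.y + MARGIN / 2),
                _round2(comp_w - 8),
                _round2(canvas.h - MARGIN),
            )
            inner = Rect(outer.x + 6, outer.y + 6, outer.w - 12, outer.h - 12)
            compartments.append(
                Compartment(f"C-SYN-{i + 1:03d}", f"compartment {i + 1}", outer, inner)
            )

    cells = rng.choice(cols * rows, size=spec.n_nodes, replace=False)
    classes = list(SchemaClass)
    nodes: list[NodeGlyph] = []
    for i, cell in enumerate(sorted(int(c) for c in cells)):
        col, row = cell % cols, cell // cols
        jx = float(rng.uniform(0, CELL_W - NODE_W - 4))
        jy = float(rng.uniform(0, CELL_H - NODE_H - 4))
        x = _round2(canvas.x + MARGIN + col * CELL_W + jx)
        y = _round2(canvas.y + MARGIN + row * CELL_H + jy)
        bounds = Rect(x, y, NODE_W, NODE_H)
        comp_id = None
        for comp in compartments:
            if comp.outer.contains_rect(bounds):
                comp_id = comp.id
                break
        nodes.append(
            NodeGlyph(
                id=f"N-SYN-{i + 1:04d}",
                schema_class=classes[i % len(classes)],
                display_name=f"Entity {i + 1}",
                bounds=bounds,
                compartment_id=comp_id,
            )
        )

    def clamp(p: Point) -> Point:
        return (
            _round2(min(max(p[0], canvas.x + 1), canvas.right - 1)),
            _round2(min(max(p[1], canvas.y + 1), canvas.bottom - 1)),
        )

    edges: list[ReactionEdge] = []
    for r in range(spec.n_reactions):
        in_idx = int(rng.integers(spec.n_nodes))
        others = sorted(
            (j for j in range(spec.n_nodes) if j != in_idx),
            key=lambda j: math.hypot(
                nodes[j].bounds.center[0] - nodes[in_idx].bounds.center[0],
                nodes[j].bounds.center[1] - nodes[in_idx].bounds.center[1],
            ),
        )
        out_idx = others[int(rng.integers(min(3, len(others))))]
        n_in, n_out = nodes[in_idx], nodes[out_idx]
        mid = (
            (n_in.bounds.center[0] + n_out.bounds.center[0]) / 2,
            (n_in.bounds.center[1] + n_out.bounds.center[1]) / 2,
        )
        reaction_point = clamp(mid)
        p_in = _boundary_point(n_in.bounds, reaction_point)
        p_out = _boundary_point(n_out.bounds, reaction_point)

        backbone: list[Point] = [p_in]
        n_bends = int(rng.integers(0, 3))
        for k in range(n_bends):
            t = (k + 1) / (n_bends + 1)
            bx = p_in[0] + t * (reaction_point[0] - p_in[0])
            by = p_in[1] + t * (reaction_point[1] - p_in[1])
            off = float(rng.uniform(-12, 12))
            backbone.append(clamp((bx - off * 0.2, by + off)))
        backbone.append(reaction_point)

        connectors = [
            Connector(ConnectorRole.INPUT, n_in.id, (p_in, reaction_point)),
            Connector(
                ConnectorRole.OUTPUT, n_out.id, (p_out, reaction_point),
                LineEnding.ARROW,
            ),
        ]
        if len(others) > 1 and rng.random() < 0.5:
            cat = nodes[others[1]]
            p_cat = _boundary_point(cat.bounds, reaction_point)
            connectors.append(
                Connector(ConnectorRole.CATALYST, cat.id, (p_cat, reaction_point),
                          LineEnding.CIRCLE)
            )
        if len(others) > 2 and rng.random() < 0.25:
            inh = nodes[others[2]]
            p_inh = _boundary_point(inh.bounds, reaction_point)
            connectors.append(
                Connector(ConnectorRole.INHIBITOR, inh.id, (p_inh, reaction_point),
                          LineEnding.BAR)
            )
        edges.append(
            ReactionEdge(
                id=f"R-SYN-RXN-{r + 1:04d}",
                reaction_point=reaction_point,
                segments=tuple(backbone),
                connectors=tuple(connectors),
            )
        )

    subpathways = None
    if spec.n_subpathways > 0 and edges:
        if spec.n_subpathways > len(edges):
            raise FixtureError("more subpathways than reactions")
        by_x = sorted(edges, key=lambda e: (e.reaction_point[0], e.id))
        chunks = np.array_split(np.arange(len(by_x)), spec.n_subpathways)
        groups = {}
        names = {}
        for i, chunk in enumerate(chunks):
            sp_id = f"R-SYN-SP-{i + 1:03d}"
            groups[sp_id] = frozenset(by_x[j].id for j in chunk)
            names[sp_id] = f"Synthetic subpathway {chr(65 + i)}"
        subpathways = SubpathwayAssignment(
            parent_pathway_id=f"R-SYN-{spec.seed:05d}",
            groups=groups,
            display_names=names,
        )

    diagram = Diagram(
        pathway_id=f"R-SYN-{spec.seed:05d}",
        canvas=canvas,
        nodes=tuple(nodes),
        edges=tuple(edges),
        compartments=tuple(compartments),
    )
    return DiagramDocument(1, diagram, subpathways)


# ---------------------------------------------------------------------------
# EHLD SVG fixtures

def ehld_pathway_ids(spec: FixtureSpec) -> list[str]:
    return [f"R-SYN-{1001 + i}" for i in range(spec.ehld_regions)]


def generate_ehld(spec: FixtureSpec) -> str:
    """Annotated SVG with ``ehld_regions`` active-region triples.

    Region shapes cycle through rect/circle/polygon/path to exercise every
    hit-testing branch, and the document always contains pure decorations
    (background, unannotated blobs) that must survive all operations
    untouched.
    """
    rng = np.random.default_rng(spec.seed + 7)
    W, H = 1200.0, 800.0
    root = etree.Element(
        f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS},
        version="1.1", viewBox=f"0 0 {W:g} {H:g}",
        width=f"{W:g}", height=f"{H:g}",
    )
    bg = etree.SubElement(root, f"{{{SVG_NS}}}rect")
    bg.set("width", f"{W:g}")
    bg.set("height", f"{H:g}")
    bg.set("fill", "#FBF7EC")
    for d in range(3):
        deco = etree.SubElement(root, f"{{{SVG_NS}}}circle")
        deco.set("id", f"deco-{d + 1}")
        deco.set("cx", f"{float(rng.uniform(0.05, 0.95)) * W:.1f}")
        deco.set("cy", f"{float(rng.uniform(0.75, 0.97)) * H:.1f}")
        deco.set("r", f"{float(rng.uniform(6, 18)):.1f}")
        deco.set("fill", "#D8CBA8")

    n = spec.ehld_regions
    if n == 0:
        return etree.tostring(root, pretty_print=True, xml_declaration=True,
                              encoding="UTF-8").decode()
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    cell_w, cell_h = W / cols, (H - 120) / rows
    palette = ["#BBDFC8", "#C8D3EB", "#EBD3C8", "#E3E0B8", "#D5C8EB",
               "#C8EBE6", "#EBC8D9", "#D9EBC8"]
    for i, pid in enumerate(ehld_pathway_ids(spec)):
        col, row = i % cols, i // cols
        x = col * cell_w + 30
        y = row * cell_h + 30
        w = cell_w - 60
        h = cell_h - 90
        fill = palette[i % len(palette)]
        kind = i % 4
        if kind == 0:
            el = etree.SubElement(root, f"{{{SVG_NS}}}rect")
            el.set("x", f"{x:.1f}")
            el.set("y", f"{y:.1f}")
            el.set("width", f"{w:.1f}")
            el.set("height", f"{h:.1f}")
            el.set("rx", "14")
        elif kind == 1:
            el = etree.SubElement(root, f"{{{SVG_NS}}}circle")
            r = min(w, h) / 2
            el.set("cx", f"{x + w / 2:.1f}")
            el.set("cy", f"{y + h / 2:.1f}")
            el.set("r", f"{r:.1f}")
        elif kind == 2:
            el = etree.SubElement(root, f"{{{SVG_NS}}}polygon")
            cx, cy = x + w / 2, y + h / 2
            pts = []
            for k in range(6):
                ang = math.pi / 3 * k
                pts.append(f"{cx + w / 2 * math.cos(ang):.1f},"
                           f"{cy + h / 2 * math.sin(ang):.1f}")
            el.set("points", " ".join(pts))
        else:
            el = etree.SubElement(root, f"{{{SVG_NS}}}path")
            el.set("d", f"M {x:.1f} {y:.1f} L {x + w:.1f} {y:.1f} "
                        f"L {x + w:.1f} {y + h:.1f} L {x:.1f} {y + h:.1f} Z")
        el.set("id", f"REGION-{pid}")
        el.set("fill", fill)
        el.set("stroke", "#7A8B7F")

        label = etree.SubElement(root, f"{{{SVG_NS}}}text")
        label.set("id", f"TEXT-{pid}")
        label.set("x", f"{x + 10:.1f}")
        label.set("y", f"{y + h + 24:.1f}")
        label.set("font-size", "18")
        label.text = f"Synthetic process {i + 1}"

        overlay = etree.SubElement(root, f"{{{SVG_NS}}}rect")
        overlay.set("id", f"OVERLAY-{pid}")
        overlay.set("x", f"{x + 8:.1f}")
        overlay.set("y", f"{y + h + 8:.1f}")
        overlay.set("width", "170")
        overlay.set("height", "24")
        overlay.set("fill", "none")
        overlay.set("stroke", "none")
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


# ---------------------------------------------------------------------------
# Hierarchy fixtures

def generate_hierarchy(spec: FixtureSpec) -> PathwayHierarchy:
    """Three-level hierarchy: root → one entry per EHLD region → two leaves."""
    mids = []
    for i, pid in enumerate(ehld_pathway_ids(spec)):
        leaves = [
            PathwayEntry(f"{pid}-L{j + 1}", f"Detail {i + 1}.{j + 1}",
                         HierarchyKind.LOWER_LEVEL)
            for j in range(2)
        ]
        mids.append(PathwayEntry(pid, f"Synthetic process {i + 1}",
                                 HierarchyKind.HIGHER_LEVEL, leaves))
    root = PathwayEntry("R-SYN-ROOT", "Synthetic root",
                        HierarchyKind.HIGHER_LEVEL, mids)
    return PathwayHierarchy(root)


def random_hierarchy(seed: int, n_entries: int) -> PathwayHierarchy:
    """Random tree with exactly ``n_entries`` entries (round-trip testing)."""
    rng = np.random.default_rng(seed)
    root = PathwayEntry("R-SYN-H-0001", "entry 1", HierarchyKind.HIGHER_LEVEL)
    inner = [root]
    count = 1
    while count < n_entries:
        count += 1
        sid = f"R-SYN-H-{count:04d}"
        parent = inner[int(rng.integers(len(inner)))]
        is_leaf = count == n_entries or rng.random() < 0.35
        kind = HierarchyKind.LOWER_LEVEL if is_leaf else HierarchyKind.HIGHER_LEVEL
        entry = PathwayEntry(sid, f"entry {count}", kind)
        parent.children.append(entry)
        if not is_leaf:
            inner.append(entry)
    return PathwayHierarchy(root)


# ---------------------------------------------------------------------------
# Analysis fixtures

def generate_analysis_fixture(
    spec: FixtureSpec,
) -> tuple[PathwayEntitySets, list[str], str]:
    """Pathway entity sets plus a query with one planted enriched pathway.

    The planted pathway contributes ``round(hit_fraction * query_size)`` of
    its members to the query; the remainder is drawn uniformly from the rest
    of the universe as background.  Returns the sets, the query and the
    planted pathway identifier.
    """
    if spec.universe_size < 10:
        raise FixtureError("universe_size must be >= 10")
    rng = np.random.default_rng(spec.seed + 13)
    universe = [f"UID{i:05d}" for i in range(spec.universe_size)]
    set_ids = [f"R-SYN-{1001 + i}" for i in range(spec.n_pathway_sets)]
    sets: dict[str, frozenset[str]] = {}
    for sid in set_ids:
        members = rng.choice(spec.universe_size, size=spec.set_size, replace=False)
        sets[sid] = frozenset(universe[int(m)] for m in members)
    planted = set_ids[int(rng.integers(len(set_ids)))]

    n_hits = min(int(round(spec.hit_fraction * spec.query_size)), spec.set_size)
    planted_members = sorted(sets[planted])
    hits = [planted_members[int(i)]
            for i in rng.choice(len(planted_members), size=n_hits, replace=False)]
    rest = sorted(set(universe) - sets[planted])
    n_bg = max(0, spec.query_size - n_hits)
    background = [rest[int(i)]
                  for i in rng.choice(len(rest), size=n_bg, replace=False)]
    query = hits + background
    rng.shuffle(query)
    return (
        PathwayEntitySets(universe=frozenset(universe), sets=sets),
        list(query),
        planted,
    )


# ---------------------------------------------------------------------------
# Fixture directories

def write_fixture_dir(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Write a complete fixture directory; returns the file map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "diagram": os.path.join(outdir, "diagram.json"),
        "hierarchy": os.path.join(outdir, "hierarchy.json"),
        "ehld": os.path.join(outdir, "ehld.svg"),
        "sets": os.path.join(outdir, "sets.gmt"),
        "query": os.path.join(outdir, "query.txt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_diagram(generate_diagram(spec), paths["diagram"])
    write_hierarchy(generate_hierarchy(spec), paths["hierarchy"])
    with open(paths["ehld"], "w", encoding="utf-8") as fh:
        fh.write(generate_ehld(spec))
    sets, query, planted = generate_analysis_fixture(spec)
    write_gmt(sets, paths["sets"])
    with open(paths["query"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(query) + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({"plantedPathway": planted, "seed": spec.seed}, fh, indent=2)
        fh.write("\n")
    return paths
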