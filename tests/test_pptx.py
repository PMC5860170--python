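"""Shape-graph construction and PPTX structural round trips."""

from __future__ import annotations

import zipfile

import pytest
from lxml import etree

from pathviz.fixtures import FixtureSpec, generate_diagram
from pathviz.model import (
    Connector,
    ConnectorRole,
    Diagram,
    LineEnding,
    NodeGlyph,
    ReactionEdge,
    Rect,
    SchemaClass,
)
from pathviz.pptx import (
    NS_A,
    NS_P,
    PptxExportError,
    build_shape_graph,
    verify_export,
    write_pptx,
)
from pathviz.profiles import MODERN


def _two_node_diagram(backbone_points) -> Diagram:
    a = NodeGlyph("N-A", SchemaClass.PROTEIN, "A", Rect(10, 10, 60, 30))
    b = NodeGlyph("N-B", SchemaClass.CHEMICAL, "B", Rect(210, 10, 60, 30))
    rp = (150.0, 25.0)
    edge = ReactionEdge(
        "R-1", rp, tuple(backbone_points),
        (
            Connector(ConnectorRole.INPUT, "N-A", ((70.0, 25.0), rp)),
            Connector(ConnectorRole.OUTPUT, "N-B", ((210.0, 25.0), rp),
                      LineEnding.ARROW),
        ),
    )
    return Diagram("P", Rect(0, 0, 300, 100), (a, b), (edge,))


def _polyline_segment_count(diagram: Diagram) -> int:
    total = 0
    for e in diagram.edges:
        if len(e.segments) >= 2:
            total += len(e.segments) - 1
        for c in e.connectors:
            if len(c.points) >= 2:
                total += len(c.points) - 1
    return total


def _interior_point_count(diagram: Diagram) -> int:
    total = 0
    for e in diagram.edges:
        if len(e.segments) >= 2:
            total += len(e.segments) - 2
        for c in e.connectors:
            if len(c.points) >= 2:
                total += len(c.points) - 2
    return total


class TestBuildShapeGraph:
    def test_straight_backbone_produces_no_anchors(self):
        diagram = _two_node_diagram([(70.0, 25.0), (150.0, 25.0)])
        graph = build_shape_graph(diagram, MODERN)
        assert graph.count("anchor") == 0
        assert graph.count("node") == 2
        assert graph.count("center") == 1
        shape_ids = {s.id for s in graph.shapes}
        node_ids = {s.id for s in graph.shapes if s.kind == "node"}
        center_id = next(s.id for s in graph.shapes if s.kind == "center")
        for conn in graph.connectors:
            assert conn.from_id in shape_ids and conn.to_id in shape_ids
        # each participant connector chains a node shape to the centre shape
        participant_conns = [c for c in graph.connectors
                             if c.from_id in node_ids and c.to_id == center_id]
        assert len(participant_conns) >= 2

    def test_two_bend_backbone_yields_two_anchors_three_connectors(self):
        diagram = _two_node_diagram(
            [(70.0, 25.0), (100.0, 45.0), (130.0, 10.0), (150.0, 25.0)]
        )
        graph = build_shape_graph(diagram, MODERN)
        assert graph.count("anchor") == 2
        backbone_conns = [c for c in graph.connectors if "backbone" in c.name]
        assert len(backbone_conns) == 3
        # chained: node -> anchor -> anchor -> centre
        anchors = {s.id for s in graph.shapes if s.kind == "anchor"}
        chain_ids = [backbone_conns[0].from_id]
        for c in backbone_conns:
            assert c.from_id == chain_ids[-1]
            chain_ids.append(c.to_id)
        assert set(chain_ids[1:-1]) == anchors

    def test_output_arrow_decorates_node_side_segment_only(self):
        diagram = _two_node_diagram([(70.0, 25.0), (150.0, 25.0)])
        graph = build_shape_graph(diagram, MODERN)
        arrowed = [c for c in graph.connectors if c.head_end == "triangle"]
        assert len(arrowed) == 1
        node_ids = {s.id for s in graph.shapes if s.kind == "node"}
        assert arrowed[0].from_id in node_ids

    def test_catalyst_circle_grouped_with_adjacent_connector(self, tiny_diagram):
        graph = build_shape_graph(tiny_diagram, MODERN)
        assert graph.count("decoration") == 1
        [group] = graph.groups
        deco = next(s for s in graph.shapes if s.kind == "decoration")
        assert deco.id in group
        conn_ids = {c.id for c in graph.connectors}
        assert len(group & conn_ids) == 1

    def test_connector_count_equals_total_segments(self):
        for seed in range(4):
            doc = generate_diagram(FixtureSpec(seed=seed))
            graph = build_shape_graph(doc.diagram, MODERN)
            assert len(graph.connectors) == _polyline_segment_count(doc.diagram)
            assert graph.count("anchor") == _interior_point_count(doc.diagram)

    def test_invalid_diagram_rejected_with_violations(self, tiny_diagram):
        import dataclasses

        edge = tiny_diagram.edges[0]
        bad_conn = dataclasses.replace(edge.connectors[0], node_id="N-GHOST")
        bad_edge = dataclasses.replace(edge,
                                       connectors=(bad_conn,) + edge.connectors[1:])
        bad = dataclasses.replace(tiny_diagram, edges=(bad_edge,))
        with pytest.raises(PptxExportError, match="N-GHOST"):
            build_shape_graph(bad, MODERN)


class TestWriteAndVerify:
    def test_single_slide_package_with_zero_defects(self, tiny_diagram, tmp_path):
        graph = build_shape_graph(tiny_diagram, MODERN)
        out = tmp_path / "tiny.pptx"
        write_pptx(graph, str(out))
        with zipfile.ZipFile(out) as zf:
            slides = [n for n in zf.namelist()
                      if n.startswith("ppt/slides/") and n.endswith(".xml")]
            assert slides == ["ppt/slides/slide1.xml"]
        report = verify_export(str(out))
        assert report.ok
        assert report.dangling_refs == 0
        assert report.unattached_connectors == 0
        assert report.out_of_bounds == 0
        assert report.connector_count == len(graph.connectors)

    def test_reopened_connectors_reference_present_shapes(
        self, diagram_doc, tmp_path
    ):
        graph = build_shape_graph(diagram_doc.diagram, MODERN)
        out = tmp_path / "fixture.pptx"
        write_pptx(graph, str(out))
        with zipfile.ZipFile(out) as zf:
            slide = etree.fromstring(zf.read("ppt/slides/slide1.xml"))
        shape_ids = {
            int(c.get("id"))
            for c in slide.iter(f"{{{NS_P}}}cNvPr")
        }
        cxns = list(slide.iter(f"{{{NS_P}}}cxnSp"))
        assert cxns
        for cxn in cxns:
            st = cxn.find(f".//{{{NS_A}}}stCxn")
            en = cxn.find(f".//{{{NS_A}}}endCxn")
            assert st is not None and en is not None
            assert int(st.get("id")) in shape_ids
            assert int(en.get("id")) in shape_ids

    def test_anchor_shapes_invisible_on_reparse(self, tmp_path):
        diagram = _two_node_diagram(
            [(70.0, 25.0), (100.0, 45.0), (150.0, 25.0)]
        )
        graph = build_shape_graph(diagram, MODERN)
        anchor_names = {s.name for s in graph.shapes if s.kind == "anchor"}
        assert anchor_names
        out = tmp_path / "anchored.pptx"
        write_pptx(graph, str(out))
        with zipfile.ZipFile(out) as zf:
            slide = etree.fromstring(zf.read("ppt/slides/slide1.xml"))
        seen = 0
        for sp in slide.iter(f"{{{NS_P}}}sp"):
            name = sp.find(f"{{{NS_P}}}nvSpPr/{{{NS_P}}}cNvPr").get("name")
            if name in anchor_names:
                seen += 1
                assert sp.find(f"{{{NS_P}}}spPr/{{{NS_A}}}noFill") is not None
                ln = sp.find(f"{{{NS_P}}}spPr/{{{NS_A}}}ln")
                assert ln.find(f"{{{NS_A}}}noFill") is not None
        assert seen == len(anchor_names)

    def test_deleted_shape_detected_as_dangling_reference(
        self, tiny_diagram, tmp_path
    ):
        graph = build_shape_graph(tiny_diagram, MODERN)
        out = tmp_path / "ok.pptx"
        write_pptx(graph, str(out))
        with zipfile.ZipFile(out) as zf:
            parts = {n: zf.read(n) for n in zf.namelist()}
        slide = etree.fromstring(parts["ppt/slides/slide1.xml"])
        node_shape_id = next(s.id for s in graph.shapes if s.kind == "node")
        for sp in slide.iter(f"{{{NS_P}}}sp"):
            cnv = sp.find(f"{{{NS_P}}}nvSpPr/{{{NS_P}}}cNvPr")
            if int(cnv.get("id")) == node_shape_id:
                sp.getparent().remove(sp)
                break
        parts["ppt/slides/slide1.xml"] = etree.tostring(slide)
        broken = tmp_path / "broken.pptx"
        with zipfile.ZipFile(broken, "w") as zf:
            for name, data in parts.items():
                zf.writestr(name, data)
        report = verify_export(str(broken))
        assert report.dangling_refs >= 1
        assert not report.ok

    def test_unreadable_file_rejected(self, tmp_path):
        junk = tmp_path / "junk.pptx"
        junk.write_bytes(b"not a zip archive")
        with pytest.raises(PptxExportError, match="unreadable export"):
            verify_export(str(junk))
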