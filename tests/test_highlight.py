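"""Highlight boxes, empty-rectangle search, label placement and fading."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import mer_bruteforce, rect_set
from pathviz.fixtures import FixtureSpec, generate_diagram
from pathviz.highlight import (
    FontModel,
    HighlightBox,
    assign_colors,
    compute_boxes,
    compute_highlights,
    fade_alpha,
    maximal_empty_rectangles,
    place_label,
)
from pathviz.model import (
    Connector,
    ConnectorRole,
    Diagram,
    NodeGlyph,
    ReactionEdge,
    Rect,
    SchemaClass,
    points_bbox,
    rect_union,
)
from pathviz.profiles import MODERN


def random_mer_instance(rng: np.random.Generator) -> tuple[Rect, list[Rect]]:
    """Random integer-coordinate container + up to 6 obstacles."""
    cw = int(rng.integers(5, 21))
    ch = int(rng.integers(5, 21))
    container = Rect(0, 0, float(cw), float(ch))
    obstacles = []
    for _ in range(int(rng.integers(0, 7))):
        x = int(rng.integers(-2, cw))
        y = int(rng.integers(-2, ch))
        w = int(rng.integers(1, cw))
        h = int(rng.integers(1, ch))
        obstacles.append(Rect(float(x), float(y), float(w), float(h)))
    return container, obstacles


class TestMaximalEmptyRectangles:
    def test_no_obstacles_returns_container(self):
        c = Rect(0, 0, 10, 10)
        assert maximal_empty_rectangles(c, []) == [c]

    def test_single_central_obstacle(self):
        got = rect_set(
            maximal_empty_rectangles(Rect(0, 0, 10, 10), [Rect(4, 4, 2, 2)])
        )
        assert got == {
            (0.0, 0.0, 10.0, 4.0),
            (0.0, 6.0, 10.0, 4.0),
            (0.0, 0.0, 4.0, 10.0),
            (6.0, 0.0, 4.0, 10.0),
        }

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            container, obstacles = random_mer_instance(rng)
            got = rect_set(maximal_empty_rectangles(container, obstacles))
            assert got == mer_bruteforce(container, obstacles)

    def test_outputs_avoid_all_obstacle_interiors(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            container, obstacles = random_mer_instance(rng)
            for r in maximal_empty_rectangles(container, obstacles):
                assert container.contains_rect(r)
                assert not any(r.intersects_interior(o) for o in obstacles)


class TestAssignColors:
    def test_cyclic_and_deterministic(self):
        pal = MODERN.subpathway_palette
        assert assign_colors(1, MODERN) == [pal[0]]
        wrapped = assign_colors(len(pal) + 1, MODERN)
        assert wrapped[-1] == pal[0]
        assert assign_colors(5, MODERN) == assign_colors(5, MODERN)


def _one_reaction_diagram() -> tuple[Diagram, Rect]:
    """Single reaction whose full geometry union is (10, 10, 100, 50)."""
    a = NodeGlyph("A", SchemaClass.PROTEIN, "A", Rect(10, 10, 30, 20))
    b = NodeGlyph("B", SchemaClass.PROTEIN, "B", Rect(80, 40, 30, 20))
    rp = (60.0, 35.0)
    edge = ReactionEdge(
        "R1", rp, ((40.0, 20.0), rp),
        (
            Connector(ConnectorRole.INPUT, "A", ((40.0, 20.0), rp)),
            Connector(ConnectorRole.OUTPUT, "B", ((80.0, 50.0), rp)),
        ),
    )
    diagram = Diagram("P", Rect(0, 0, 400, 300), (a, b), (edge,))
    union = rect_union([a.bounds, b.bounds, points_bbox(edge.all_points())])
    assert union == Rect(10, 10, 100, 50)
    return diagram, union


class TestComputeBoxes:
    def test_padded_bounding_box(self):
        from pathviz.model import SubpathwayAssignment

        diagram, _ = _one_reaction_diagram()
        assignment = SubpathwayAssignment("P", {"SP1": frozenset({"R1"})})
        [box] = compute_boxes(diagram, assignment, padding=8, profile=MODERN)
        assert box.box == Rect(2, 2, 116, 66)

    def test_zero_padding_equals_reaction_bounds(self):
        from pathviz.model import SubpathwayAssignment

        diagram, union = _one_reaction_diagram()
        assignment = SubpathwayAssignment("P", {"SP1": frozenset({"R1"})})
        [box] = compute_boxes(diagram, assignment, padding=0, profile=MODERN)
        assert box.box == union

    def test_every_member_point_inside_its_box(self, diagram_doc):
        boxes = {
            b.subpathway_id: b
            for b in compute_boxes(
                diagram_doc.diagram, diagram_doc.subpathways, 10, MODERN
            )
        }
        edges = diagram_doc.diagram.edge_by_id()
        for sp_id, members in diagram_doc.subpathways.groups.items():
            box = boxes[sp_id].box
            for rid in members:
                for p in edges[rid].all_points():
                    assert box.contains_point(p)

    def test_unknown_reaction_rejected_naming_subpathway(self, diagram_doc):
        from pathviz.highlight import HighlightError
        from pathviz.model import SubpathwayAssignment

        bad = SubpathwayAssignment("P", {"SP-GHOST": frozenset({"R-NOPE"})})
        with pytest.raises(HighlightError, match="SP-GHOST"):
            compute_boxes(diagram_doc.diagram, bad, 8, MODERN)


class TestPlaceLabel:
    def test_alone_gets_interior_minus_margin(self):
        box = HighlightBox("SP1", Rect(0, 0, 200, 100), "#FF000060", "Label")
        placed = place_label(box, [box], inner_margin=4)
        assert placed.label_rect == Rect(4, 4, 192, 92)
        assert placed.font_size is not None

    def test_fully_covered_label_omitted(self):
        target = HighlightBox("SP1", Rect(0, 0, 100, 40), "#FF000060", "Label")
        cover = HighlightBox("SP2", Rect(-10, -10, 200, 100), "#00FF0060", "Other")
        placed = place_label(target, [target, cover])
        assert placed.label_rect is None and placed.font_size is None

    def test_half_overlap_pushes_label_to_free_strip(self):
        target = HighlightBox("SP1", Rect(0, 0, 100, 40), "#FF000060", "AB")
        other = HighlightBox("SP2", Rect(0, 0, 100, 20), "#00FF0060", "CD")
        placed = place_label(target, [target, other], inner_margin=0)
        assert placed.label_rect is not None
        assert Rect(0, 20, 100, 20).contains_rect(placed.label_rect)

    def test_invariant_under_permutation_of_boxes(self):
        rng = np.random.default_rng(3)
        boxes = [
            HighlightBox(
                f"SP{i}",
                Rect(float(rng.integers(0, 200)), float(rng.integers(0, 120)),
                     float(rng.integers(60, 160)), float(rng.integers(40, 90))),
                "#11223360",
                f"Subpathway {i}",
            )
            for i in range(5)
        ]
        target = boxes[2]
        ref = place_label(target, boxes)
        for _ in range(5):
            perm = list(boxes)
            rng.shuffle(perm)
            assert place_label(target, perm) == ref


class TestFontModel:
    def test_greedy_wrap_keeps_lines_within_width(self):
        fm = FontModel()
        lines = fm.wrap("alpha beta gamma delta", width=60, font_size=10)
        assert lines is not None and len(lines) > 1
        assert all(fm.text_width(line, 10) <= 60 for line in lines)

    def test_unsplittable_word_fails(self):
        assert FontModel().wrap("supercalifragilistic", width=30, font_size=10) is None


class TestFadeAlpha:
    @pytest.mark.parametrize(
        "zoom,expected", [(0.5, 1.0), (1.2, 0.0), (0.8, 0.5)]
    )
    def test_linear_ramp_defaults(self, zoom, expected):
        assert fade_alpha(zoom, 0.6, 1.0) == pytest.approx(expected)

    def test_monotone_nonincreasing_and_clamped(self):
        rng = np.random.default_rng(0)
        zooms = np.sort(rng.uniform(0.01, 3.0, size=1000))
        alphas = [fade_alpha(z, 0.6, 1.0) for z in zooms]
        assert all(0.0 <= a <= 1.0 for a in alphas)
        assert all(a1 >= a2 for a1, a2 in zip(alphas, alphas[1:]))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            fade_alpha(0.5, 1.0, 1.0)


class TestDeterminism:
    def test_two_runs_serialize_identically(self, diagram_doc):
        import json

        runs = [
            json.dumps(
                [
                    b.serialize()
                    for b in compute_highlights(
                        diagram_doc.diagram, diagram_doc.subpathways, MODERN
                    )
                ],
                sort_keys=True,
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
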