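from __future__ import annotations

import pytest

from pathviz.fixtures import FixtureSpec, generate_diagram, generate_ehld
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
from pathviz.profiles import MODERN


@pytest.fixture
def profile():
    return MODERN


@pytest.fixture
def spec():
    return FixtureSpec(seed=11)


@pytest.fixture
def diagram_doc(spec):
    return generate_diagram(spec)


@pytest.fixture
def ehld_svg(spec):
    return generate_ehld(spec)


def make_tiny_diagram() -> Diagram:
    """Well-formed 3-node, 1-reaction diagram with every participant role."""
    a = NodeGlyph("N-A", SchemaClass.PROTEIN, "Kinase A", Rect(10, 10, 60, 30))
    b = NodeGlyph("N-B", SchemaClass.CHEMICAL, "Metabolite B", Rect(210, 10, 60, 30))
    c = NodeGlyph("N-C", SchemaClass.PROTEIN, "Enzyme C", Rect(110, 100, 60, 30))
    rp = (140.0, 25.0)
    edge = ReactionEdge(
        id="R-1",
        reaction_point=rp,
        segments=((70.0, 25.0), rp),
        connectors=(
            Connector(ConnectorRole.INPUT, "N-A", ((70.0, 25.0), rp)),
            Connector(ConnectorRole.OUTPUT, "N-B", ((210.0, 25.0), rp),
                      LineEnding.ARROW),
            Connector(ConnectorRole.CATALYST, "N-C", ((140.0, 100.0), rp),
                      LineEnding.CIRCLE),
        ),
    )
    return Diagram(
        pathway_id="R-TINY",
        canvas=Rect(0, 0, 300, 160),
        nodes=(a, b, c),
        edges=(edge,),
    )


@pytest.fixture
def tiny_diagram() -> Diagram:
    return make_tiny_diagram()
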