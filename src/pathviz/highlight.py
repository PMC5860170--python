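"""Subpathway highlight boxes and label placement.

A classic lower-level pathway diagram is partitioned into subpathways; each
gets a coloured, semi-transparent box bounding the geometry of its member
reactions.  Box positions and colours are pure functions of the diagram and
assignment, so a release-time precomputation yields identical results on
every run — the boxes persist unchanged for the lifetime of a data release.

Label placement uses a space-partitioning approach: the obstacles are the
overlaps of every *other* subpathway box with the target box, and the label
goes into the largest (ties: widest, then topmost, then leftmost) axis-aligned
empty rectangle among them.  The font is then shrunk, with greedy word
wrapping under a deterministic device-independent font metric, until the text
fits; labels that would drop below a minimum legible size are omitted.

Highlight boxes are drawn in zoomed-out views and fade out linearly as the
user zooms toward reaction-level detail (:func:`fade_alpha`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .model import (
    Diagram,
    Rect,
    SubpathwayAssignment,
    rect_union,
    points_bbox,
    validate_assignment,
)
from .profiles import ColorProfile

DEFAULT_MIN_FONT = 8.0
DEFAULT_MAX_FONT = 24.0
DEFAULT_INNER_MARGIN = 4.0
DEFAULT_FADE_START = 0.6
DEFAULT_FADE_END = 1.0


class HighlightError(ValueError):
    pass


@dataclass(frozen=True)
class HighlightBox:
    """One subpathway's highlight box, optionally with a placed label.

    ``label_rect``/``font_size`` are absent when no legible label fits.  The
    ``overlay_fill``/``bar``/``annotation`` fields are populated by the
    analysis overlay when enrichment results are projected onto the box.
    """

    subpathway_id: str
    box: Rect
    fill: str
    label_text: str
    label_rect: Optional[Rect] = None
    font_size: Optional[float] = None
    overlay_fill: Optional[str] = None
    bar: Optional[Rect] = None
    annotation: Optional[str] = None

    def serialize(self) -> dict:
        out: dict = {
            "subpathwayId": self.subpathway_id,
            "box": [self.box.x, self.box.y, self.box.w, self.box.h],
            "fill": self.fill,
            "labelText": self.label_text,
        }
        if self.label_rect is not None:
            r = self.label_rect
            out["labelRect"] = [r.x, r.y, r.w, r.h]
            out["fontSize"] = self.font_size
        return out


@dataclass(frozen=True)
class FontModel:
    """Approximate, device-independent font metric.

    Character advance is a fixed fraction of the font size and line height a
    fixed multiple; greedy word wrap.  Crude, but fully deterministic — the
    same label always fits (or not) the same rectangle regardless of the
    rendering device.
    """

    char_width_ratio: float = 0.6
    line_height_ratio: float = 1.2

    def text_width(self, text: str, font_size: float) -> float:
        return len(text) * self.char_width_ratio * font_size

    def wrap(self, text: str, width: float, font_size: float) -> Optional[list[str]]:
        """Greedy word wrap; None when some single word cannot fit."""
        words = text.split()
        if not words:
            return []
        lines: list[str] = []
        current = ""
        for word in words:
            if self.text_width(word, font_size) > width:
                return None
            candidate = word if not current else current + " " + word
            if self.text_width(candidate, font_size) <= width:
                current = candidate
            else:
                lines.append(current)
                current = word
        lines.append(current)
        return lines

    def fits(self, text: str, rect: Rect, font_size: float) -> Optional[list[str]]:
        lines = self.wrap(text, rect.w, font_size)
        if lines is None:
            return None
        if len(lines) * self.line_height_ratio * font_size > rect.h:
            return None
        return lines


def assign_colors(n: int, profile: ColorProfile) -> list[str]:
    """Cyclic assignment from the profile palette; pure function of n."""
    if n < 1:
        raise HighlightError("need at least one subpathway to colour")
    pal = profile.subpathway_palette
    return [pal[i % len(pal)] for i in range(n)]


def compute_boxes(
    diagram: Diagram,
    assignment: SubpathwayAssignment,
    padding: float,
    profile: ColorProfile,
) -> list[HighlightBox]:
    """Padded bounding boxes of each subpathway's reaction geometry.

    The box bounds every backbone point, connector point and participating
    node glyph of the subpathway's reactions, grows by ``padding`` on each
    side, and is clipped to the canvas.  Subpathways are processed in sorted
    identifier order so colour assignment is reproducible.
    """
    problems = validate_assignment(diagram, assignment)
    if problems:
        raise HighlightError("; ".join(problems))
    edges = diagram.edge_by_id()
    nodes = diagram.node_by_id()

    sp_ids = sorted(assignment.groups)
    colors = assign_colors(len(sp_ids), profile)
    boxes: list[HighlightBox] = []
    for sp_id, fill in zip(sp_ids, colors):
        members = assignment.groups[sp_id]
        rects: list[Rect] = []
        for rid in sorted(members):
            edge = edges[rid]
            rects.append(points_bbox(edge.all_points()))
            for conn in edge.connectors:
                rects.append(nodes[conn.node_id].bounds)
        if not rects:
            raise HighlightError(f"subpathway '{sp_id}' has no resolvable reactions")
        box = rect_union(rects)
        if box.w == 0 and box.h == 0:
            # all geometry at a single point: give it a 2*padding square
            box = Rect(box.x - padding, box.y - padding, 2 * padding, 2 * padding)
        else:
            box = box.padded(padding)
        clipped = box.intersect(diagram.canvas)
        if clipped is not None:
            box = clipped
        label = assignment.display_names.get(sp_id, sp_id)
        boxes.append(HighlightBox(sp_id, box, fill, label))
    return boxes


def maximal_empty_rectangles(container: Rect, obstacles: Sequence[Rect]) -> list[Rect]:
    """All maximal axis-aligned empty rectangles inside ``container``.

    A rectangle is *empty* when its interior meets no obstacle interior, and
    *maximal* when no other empty rectangle strictly contains it.  The search
    exploits the fact that every maximal empty rectangle is supported on each
    side by an obstacle edge or the container boundary: candidate vertical
    strips come from the compressed x-coordinates, and within each strip the
    free y-gaps between the obstacles overlapping it give the candidates,
    which are then filtered for pairwise containment.
    """
    clipped = [r for r in (o.intersect(container) for o in obstacles) if r is not None]
    xs = sorted({container.x, container.right, *(r.x for r in clipped), *(r.right for r in clipped)})

    candidates: list[Rect] = []
    for i, x1 in enumerate(xs):
        for x2 in xs[i + 1 :]:
            # obstacles whose interior overlaps the open strip (x1, x2)
            blocking = sorted(
                ((o.y, o.bottom) for o in clipped if o.x < x2 and o.right > x1),
                key=lambda iv: iv[0],
            )
            y = container.y
            for oy, ob in blocking:
                if oy > y:
                    candidates.append(Rect(x1, y, x2 - x1, oy - y))
                y = max(y, ob)
            if container.bottom > y:
                candidates.append(Rect(x1, y, x2 - x1, container.bottom - y))

    unique = list({(r.x, r.y, r.w, r.h): r for r in candidates}.values())
    maximal = [
        r
        for r in unique
        if not any(other is not r and other.contains_rect(r) for other in unique)
    ]
    maximal.sort(key=lambda r: (r.x, r.y, r.w, r.h))
    return maximal


def _best_rect(rects: Sequence[Rect]) -> Optional[Rect]:
    """Largest area, ties broken by width, then topmost, then leftmost."""
    if not rects:
        return None
    return min(rects, key=lambda r: (-r.area, -r.w, r.y, r.x))


def place_label(
    target: HighlightBox,
    all_boxes: Sequence[HighlightBox],
    font_model: FontModel = FontModel(),
    min_font: float = DEFAULT_MIN_FONT,
    max_font: float = DEFAULT_MAX_FONT,
    inner_margin: float = DEFAULT_INNER_MARGIN,
) -> HighlightBox:
    """Place the subpathway label in the best empty rectangle of its box.

    The container is the target box shrunk by ``inner_margin``; the obstacles
    are the other boxes' overlaps with it.  The label is set in the largest,
    widest candidate at the biggest font ``<= max_font`` that fits; if even
    ``min_font`` does not fit, the label is omitted.
    """
    try:
        container = target.box.padded(-inner_margin)
    except ValueError:
        return replace(target, label_rect=None, font_size=None)
    if container.w <= 0 or container.h <= 0:
        return replace(target, label_rect=None, font_size=None)

    obstacles = [
        b.box
        for b in all_boxes
        if b.subpathway_id != target.subpathway_id
        and b.box.intersects_interior(container)
    ]
    candidate = _best_rect(maximal_empty_rectangles(container, obstacles))
    if candidate is None:
        return replace(target, label_rect=None, font_size=None)

    size = float(int(max_font))
    while size >= min_font:
        if font_model.fits(target.label_text, candidate, size) is not None:
            return replace(target, label_rect=candidate, font_size=size)
        size -= 1.0
    return replace(target, label_rect=None, font_size=None)


def place_all_labels(
    boxes: Sequence[HighlightBox],
    font_model: FontModel = FontModel(),
    min_font: float = DEFAULT_MIN_FONT,
    max_font: float = DEFAULT_MAX_FONT,
    inner_margin: float = DEFAULT_INNER_MARGIN,
) -> list[HighlightBox]:
    return [
        place_label(b, boxes, font_model, min_font, max_font, inner_margin)
        for b in boxes
    ]


def compute_highlights(
    diagram: Diagram,
    assignment: SubpathwayAssignment,
    profile: ColorProfile,
    padding: float = 10.0,
    font_model: FontModel = FontModel(),
    min_font: float = DEFAULT_MIN_FONT,
    max_font: float = DEFAULT_MAX_FONT,
    inner_margin: float = DEFAULT_INNER_MARGIN,
) -> list[HighlightBox]:
    """Boxes plus labels in one deterministic pass (release-time entrypoint)."""
    boxes = compute_boxes(diagram, assignment, padding, profile)
    return place_all_labels(boxes, font_model, min_font, max_font, inner_margin)


def fade_alpha(
    zoom: float,
    fade_start: float = DEFAULT_FADE_START,
    fade_end: float = DEFAULT_FADE_END,
) -> float:
    """Highlight opacity at a zoom level: 1 when zoomed out, 0 when zoomed in.

    Linear ramp from ``fade_start`` to ``fade_end``; continuous, nonincreasing
    and clamped to [0, 1].
    """
    if fade_start >= fade_end:
        raise HighlightError("fade_start must be below fade_end")
    if zoom <= fade_start:
        return 1.0
    if zoom >= fade_end:
        return 0.0
    return (fade_end - zoom) / (fade_end - fade_start)
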