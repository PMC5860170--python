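"""Independent brute-force oracles used by the test suite.

Each oracle deliberately takes a different computational route from the
library implementation it checks: exhaustive enumeration over compressed
coordinate grids for empty rectangles, exact rational summation for the
hypergeometric tail, the literal step-up definition for the FDR, and a
hand-rolled ray-casting containment test for SVG shapes.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction

from pathviz.model import Rect


# ---------------------------------------------------------------------------
# Maximal empty rectangles: exhaustive enumeration on the compressed grid

def _interiors_overlap(a: Rect, b: Rect) -> bool:
    return a.x < b.right and b.x < a.right and a.y < b.bottom and b.y < a.bottom


def mer_bruteforce(container: Rect, obstacles: list[Rect]) -> set[tuple]:
    """All maximal empty rectangles by testing every grid-aligned candidate."""
    clipped = [r for r in (o.intersect(container) for o in obstacles) if r is not None]
    xs = sorted({container.x, container.right,
                 *(r.x for r in clipped), *(r.right for r in clipped)})
    ys = sorted({container.y, container.bottom,
                 *(r.y for r in clipped), *(r.bottom for r in clipped)})
    empties: list[Rect] = []
    for i, x1 in enumerate(xs):
        for x2 in xs[i + 1:]:
            for j, y1 in enumerate(ys):
                for y2 in ys[j + 1:]:
                    cand = Rect(x1, y1, x2 - x1, y2 - y1)
                    if not any(_interiors_overlap(cand, o) for o in clipped):
                        empties.append(cand)
    maximal = [
        r for r in empties
        if not any(o is not r and o.contains_rect(r) and
                   (o.x, o.y, o.w, o.h) != (r.x, r.y, r.w, r.h)
                   for o in empties)
    ]
    return {(r.x, r.y, r.w, r.h) for r in maximal}


def rect_set(rects) -> set[tuple]:
    return {(r.x, r.y, r.w, r.h) for r in rects}


# ---------------------------------------------------------------------------
# Hypergeometric upper tail by exact rational summation

def hypergeom_tail_exact(k: int, M: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(M, n, N), exact rational arithmetic."""
    total = math.comb(M, N)
    upper = min(n, N)
    acc = Fraction(0)
    for i in range(max(k, 0), upper + 1):
        acc += Fraction(math.comb(n, i) * math.comb(M - n, N - i), total)
    return acc


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by the literal step-up definition

def bh_stepup_enum(p_values: list[float]) -> list[float]:
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            later_idx = order[later_pos - 1]
            candidates.append(p_values[later_idx] * m / later_pos)
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


# ---------------------------------------------------------------------------
# SVG shape containment by ray casting / direct formulae

_FLOAT_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _floats(s: str) -> list[float]:
    return [float(m) for m in _FLOAT_RE.findall(s)]


def _polygon_contains_raycast(pts: list[tuple[float, float]],
                              px: float, py: float) -> bool:
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def svg_element_contains(el, px: float, py: float) -> bool:
    """Independent containment check for the shapes the fixtures emit."""
    tag = el.tag.rsplit("}", 1)[-1]
    g = lambda k, d="0": float(el.get(k, d))
    if tag == "rect":
        return g("x") <= px <= g("x") + g("width") and \
               g("y") <= py <= g("y") + g("height")
    if tag == "circle":
        return (px - g("cx")) ** 2 + (py - g("cy")) ** 2 <= g("r") ** 2
    if tag == "ellipse":
        rx, ry = g("rx"), g("ry")
        return rx > 0 and ry > 0 and \
            ((px - g("cx")) / rx) ** 2 + ((py - g("cy")) / ry) ** 2 <= 1.0
    if tag == "polygon":
        vals = _floats(el.get("points", ""))
        pts = list(zip(vals[::2], vals[1::2]))
        return len(pts) >= 3 and _polygon_contains_raycast(pts, px, py)
    if tag == "path":
        vals = _floats(el.get("d", ""))
        xs, ys = vals[::2], vals[1::2]
        return bool(xs) and min(xs) <= px <= max(xs) and min(ys) <= py <= max(ys)
    if tag == "g":
        return any(svg_element_contains(c, px, py) for c in el)
    return False
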