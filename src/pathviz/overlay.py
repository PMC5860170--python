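"""Over-representation analysis and its visual overlay.

The statistic is the classic hypergeometric upper tail: with a universe of
``M`` entities, a pathway containing ``n`` of them, and an (effective) query
of ``N`` identifiers drawn from the universe, the p-value of observing ``k``
or more query members in the pathway is ``P(X >= k)`` for
``X ~ Hypergeom(M, n, N)``.  P-values are adjusted across all tested pathways
with the Benjamini–Hochberg step-up false discovery rate.

Visually, each subpathway label is covered by a rectangle whose colour
encodes the p-value (a linear gradient up to the significance threshold,
grey at or beyond it) and underlined by a bar whose width is exactly the hit
fraction ``found/total`` of the label width.  The hit count and FDR are
written next to the label, and a vertical legend bar (gradient plus grey
block) on the right edge carries a tick per displayed p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from lxml import etree
from scipy.stats import hypergeom

from .ehld import OVERLAY_GROUP_ID, SVG_NS, EhldDocument, element_bbox
from .highlight import HighlightBox
from .model import Rect
from .profiles import ColorProfile, lerp_color, svg_fill_attrs

logger = logging.getLogger(__name__)

DEFAULT_SIGNIFICANCE_THRESHOLD = 0.05
DEFAULT_BAR_HEIGHT = 4.0


class OraError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayEntitySets:
    """Pathway → entity-set definitions over a common identifier universe."""

    universe: frozenset[str]
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.universe:
            raise OraError("empty entity universe")
        for pid, members in self.sets.items():
            if not members:
                raise OraError(f"pathway set '{pid}' is empty")
            if not members <= self.universe:
                raise OraError(f"pathway set '{pid}' not contained in universe")


@dataclass(frozen=True)
class PathwayStats:
    found: int
    total: int
    p_value: float
    fdr: float


@dataclass(frozen=True)
class AnalysisResult:
    entries: dict[str, PathwayStats]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries

    def __getitem__(self, pathway_id: str) -> PathwayStats:
        return self.entries[pathway_id]


@dataclass(frozen=True)
class OverlayStyle:
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
    gradient: tuple[str, str] = ("#FFFF33", "#FF6600")
    grey: str = "#C8C8C8"
    bar_color: str = "#FFD700"
    bar_height: float = DEFAULT_BAR_HEIGHT
    legend_width: float = 16.0
    legend_margin: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_threshold < 1.0):
            raise OraError("significance threshold must lie strictly in (0, 1)")

    @classmethod
    def from_profile(
        cls, profile: ColorProfile, threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
    ) -> "OverlayStyle":
        return cls(
            significance_threshold=threshold,
            gradient=profile.overlay_gradient,
            grey=profile.not_significant_color,
            bar_color=profile.hit_bar_color,
        )


# ---------------------------------------------------------------------------
# Statistics

def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment.

    ``adj_(i) = min_{k >= i} p_(k) * m / k`` over the sorted p-values, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise OraError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def ora(query: Iterable[str], sets: PathwayEntitySets) -> AnalysisResult:
    """Hypergeometric over-representation test of a query identifier set.

    Identifiers outside the universe are dropped (with a logged count); an
    empty effective query is an error.  The upper-tail probability is
    computed by scipy's hypergeometric survival function, which works in
    log-space and is stable for large sets.
    """
    qset = set(query)
    effective = qset & sets.universe
    dropped = len(qset) - len(effective)
    if dropped:
        logger.info("dropped %d query identifiers outside the universe", dropped)
    if not effective:
        raise OraError("query disjoint from universe")

    M = len(sets.universe)
    N = len(effective)
    pathway_ids = sorted(sets.sets)
    stats: dict[str, tuple[int, int, float]] = {}
    for pid in pathway_ids:
        members = sets.sets[pid]
        n = len(members)
        k = len(effective & members)
        p = float(hypergeom.sf(k - 1, M, n, N))
        p = min(1.0, max(0.0, p))
        stats[pid] = (k, n, p)
    fdrs = bh_fdr([stats[pid][2] for pid in pathway_ids])
    entries = {
        pid: PathwayStats(found=k, total=n, p_value=p, fdr=max(f, p))
        for pid, (k, n, p), f in zip(
            pathway_ids, (stats[pid] for pid in pathway_ids), fdrs
        )
    }
    return AnalysisResult(entries)


# ---------------------------------------------------------------------------
# Visual mapping

def pvalue_to_color(p: float, style: OverlayStyle) -> str:
    """Gradient colour below the significance threshold, grey at or above."""
    if not (0.0 <= p <= 1.0):
        raise OraError(f"p-value out of range: {p}")
    thr = style.significance_threshold
    if p >= thr:
        return style.grey
    return lerp_color(style.gradient[0], style.gradient[1], p / thr)


def hit_bar_rect(
    found: int, total: int, label_box: Rect, bar_height: float = DEFAULT_BAR_HEIGHT
) -> Rect:
    """Bar under the label whose width is exactly found/total of its width."""
    if total <= 0:
        raise OraError("total must be positive")
    if not (0 <= found <= total):
        raise OraError(f"found={found} outside [0, total={total}]")
    return Rect(label_box.x, label_box.bottom, (found / total) * label_box.w, bar_height)


def format_annotation(stats: PathwayStats) -> str:
    return f"{stats.found}/{stats.total}  FDR = {stats.fdr:.2E}"


# ---------------------------------------------------------------------------
# EHLD overlay

def _strip_overlay(root: etree._Element) -> None:
    for el in list(root.iter(f"{{{SVG_NS}}}g")):
        if el.get("id") == OVERLAY_GROUP_ID:
            el.getparent().remove(el)


def _add_legend(
    group: etree._Element,
    canvas: Rect,
    style: OverlayStyle,
    displayed_p: Sequence[float],
) -> None:
    """Vertical legend: p-value gradient on top, grey block below, one tick
    per displayed p-value."""
    width = style.legend_width
    x = canvas.right - style.legend_margin - width
    y = canvas.y + style.legend_margin
    height = canvas.h - 2 * style.legend_margin
    grad_h = 0.8 * height
    grey_h = height - grad_h
    legend = etree.SubElement(group, f"{{{SVG_NS}}}g")
    legend.set("id", "analysis-legend")
    steps = 24
    for i in range(steps):
        t = (i + 0.5) / steps
        color = lerp_color(style.gradient[0], style.gradient[1], t)
        seg = etree.SubElement(legend, f"{{{SVG_NS}}}rect")
        seg.set("x", f"{x:g}")
        seg.set("y", f"{y + grad_h * i / steps:g}")
        seg.set("width", f"{width:g}")
        seg.set("height", f"{grad_h / steps:g}")
        seg.set("fill", color.rstrip()[:7])
        seg.set("class", "legend-step")
    grey = etree.SubElement(legend, f"{{{SVG_NS}}}rect")
    grey.set("x", f"{x:g}")
    grey.set("y", f"{y + grad_h:g}")
    grey.set("width", f"{width:g}")
    grey.set("height", f"{grey_h:g}")
    grey.set("fill", style.grey[:7])
    grey.set("class", "legend-grey")
    for p in sorted(displayed_p):
        if p < style.significance_threshold:
            ty = y + grad_h * (p / style.significance_threshold)
        else:
            ty = y + grad_h + grey_h / 2
        tick = etree.SubElement(legend, f"{{{SVG_NS}}}line")
        tick.set("x1", f"{x - 4:g}")
        tick.set("x2", f"{x + width:g}")
        tick.set("y1", f"{ty:g}")
        tick.set("y2", f"{ty:g}")
        tick.set("stroke", "#000000")
        tick.set("class", "legend-tick")


def apply_overlay(
    doc: EhldDocument, result: AnalysisResult, style: OverlayStyle
) -> EhldDocument:
    """Project analysis results onto an EHLD (in place; returns the document).

    For every active region with a result entry, the overlay target is
    covered by a p-value-coloured rectangle, a hit bar is drawn under it, and
    the hit count and FDR are written beside the label.  All added elements
    live in a single ``analysis-overlay`` group; re-applying replaces it, so
    the operation is idempotent, and stripping the group recovers the
    original document.
    """
    _strip_overlay(doc.root)
    displayed: list[float] = []
    group = etree.SubElement(doc.root, f"{{{SVG_NS}}}g")
    group.set("id", OVERLAY_GROUP_ID)
    skipped = 0
    for region in doc.regions:
        if region.pathway_id not in result:
            continue
        stats = result[region.pathway_id]
        target = region.overlay_ref if region.overlay_ref is not None else region.label_ref
        if target is None:
            skipped += 1
            continue
        bbox = element_bbox(target)
        if bbox is None or bbox.w == 0 or bbox.h == 0:
            skipped += 1
            continue
        color = pvalue_to_color(stats.p_value, style)
        rect = etree.SubElement(group, f"{{{SVG_NS}}}rect")
        rect.set("x", f"{bbox.x:g}")
        rect.set("y", f"{bbox.y:g}")
        rect.set("width", f"{bbox.w:g}")
        rect.set("height", f"{bbox.h:g}")
        for k, v in svg_fill_attrs(color).items():
            rect.set(k, v)
        rect.set("class", "overlay-rect")
        rect.set("data-pathway", region.pathway_id)

        bar = hit_bar_rect(stats.found, stats.total, bbox, style.bar_height)
        bar_el = etree.SubElement(group, f"{{{SVG_NS}}}rect")
        bar_el.set("x", f"{bar.x:g}")
        bar_el.set("y", f"{bar.y:g}")
        bar_el.set("width", f"{bar.w:.6g}")
        bar_el.set("height", f"{bar.h:g}")
        bar_el.set("fill", style.bar_color[:7])
        bar_el.set("class", "hit-bar")
        bar_el.set("data-pathway", region.pathway_id)

        text = etree.SubElement(group, f"{{{SVG_NS}}}text")
        text.set("x", f"{bbox.right + 4:g}")
        text.set("y", f"{bbox.bottom:g}")
        text.set("font-size", "9")
        text.set("class", "overlay-annotation")
        text.text = format_annotation(stats)
        displayed.append(stats.p_value)
    if skipped:
        logger.info("skipped %d regions without usable overlay targets", skipped)
    if displayed:
        _add_legend(group, doc.canvas, style, displayed)
    else:
        doc.root.remove(group)
    return doc


def overlay_lld_labels(
    boxes: Sequence[HighlightBox], result: AnalysisResult, style: OverlayStyle
) -> list[HighlightBox]:
    """Decorate classic-diagram subpathway labels with analysis results.

    Each labelled box with a matching result gains the p-value colour, the
    proportional hit bar under its label rectangle and the count/FDR
    annotation; boxes without results pass through unchanged.
    """
    out: list[HighlightBox] = []
    for box in boxes:
        if box.label_rect is None or box.subpathway_id not in result:
            out.append(box)
            continue
        stats = result[box.subpathway_id]
        out.append(
            replace(
                box,
                overlay_fill=pvalue_to_color(stats.p_value, style),
                bar=hit_bar_rect(stats.found, stats.total, box.label_rect, style.bar_height),
                annotation=format_annotation(stats),
            )
        )
    return out


# ---------------------------------------------------------------------------
# File formats: GMT pathway sets and query lists

def read_gmt(path: str) -> PathwayEntitySets:
    """Read pathway entity sets from a GMT-style tab-separated file.

    Each line: set name, description, then member identifiers.  The universe
    is the union of all members.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OraError(f"{path}:{lineno}: GMT line needs name, "
                               "description and at least one member")
            name = parts[0]
            if name in sets:
                raise OraError(f"{path}:{lineno}: duplicate set name '{name}'")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise OraError(f"{path}:{lineno}: set '{name}' has no members")
            sets[name] = members
    if not sets:
        raise OraError(f"{path}: no pathway sets found")
    universe = frozenset().union(*sets.values())
    return PathwayEntitySets(universe=universe, sets=sets)


def write_gmt(sets: PathwayEntitySets, path: str,
              descriptions: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets.sets):
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets.sets[name])]) + "\n")


def read_query(path: str) -> list[str]:
    """One identifier per line; blank lines and #-comments ignored."""
    out: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out
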