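"""Colour profiles and colour arithmetic.

Colours are 8-bit RGB(A) hex strings (``#RRGGBB`` or ``#RRGGBBAA``).  A
:class:`ColorProfile` bundles everything colour-related: per-glyph-class
fills and strokes, the cyclic semi-transparent palette used for subpathway
highlight boxes, the p-value gradient of the analysis overlay, the grey used
for non-significant pathways and the hit-bar yellow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import SchemaClass

RGBA = tuple[int, int, int, int]


def parse_color(color: str) -> RGBA:
    """Parse ``#RRGGBB`` / ``#RRGGBBAA`` into an (r, g, b, a) tuple."""
    s = color.lstrip("#")
    if len(s) == 6:
        s += "FF"
    if len(s) != 8:
        raise ValueError(f"invalid colour {color!r}")
    try:
        return tuple(int(s[i : i + 2], 16) for i in (0, 2, 4, 6))  # type: ignore[return-value]
    except ValueError as exc:
        raise ValueError(f"invalid colour {color!r}") from exc


def format_color(rgba: RGBA) -> str:
    r, g, b, a = (max(0, min(255, int(round(v)))) for v in rgba)
    if a == 255:
        return f"#{r:02X}{g:02X}{b:02X}"
    return f"#{r:02X}{g:02X}{b:02X}{a:02X}"


def lerp_color(c0: str, c1: str, t: float) -> str:
    """Componentwise linear interpolation between two colours, t in [0, 1]."""
    a = parse_color(c0)
    b = parse_color(c1)
    t = max(0.0, min(1.0, t))
    return format_color(tuple(a[i] + (b[i] - a[i]) * t for i in range(4)))  # type: ignore[arg-type]


def svg_fill_attrs(color: str) -> dict[str, str]:
    """Split an RGBA hex into SVG ``fill`` + ``fill-opacity`` attributes."""
    r, g, b, a = parse_color(color)
    attrs = {"fill": f"#{r:02X}{g:02X}{b:02X}"}
    if a != 255:
        attrs["fill-opacity"] = f"{a / 255:.3f}"
    return attrs


@dataclass(frozen=True)
class ColorProfile:
    name: str
    node_fill: dict[SchemaClass, str]
    node_stroke: dict[SchemaClass, str]
    subpathway_palette: tuple[str, ...]
    overlay_gradient: tuple[str, str]  # colour at p = 0, colour at p = threshold
    not_significant_color: str
    hit_bar_color: str

    def __post_init__(self) -> None:
        if len(self.subpathway_palette) < 8:
            raise ValueError("subpathway palette needs at least 8 colours")
        if len(set(self.subpathway_palette)) != len(self.subpathway_palette):
            raise ValueError("subpathway palette colours must be distinct")
        for c in (
            *self.node_fill.values(),
            *self.node_stroke.values(),
            *self.subpathway_palette,
            *self.overlay_gradient,
            self.not_significant_color,
            self.hit_bar_color,
        ):
            parse_color(c)


_FILLS_MODERN = {
    SchemaClass.PROTEIN: "#8DC7BB",
    SchemaClass.CHEMICAL: "#A5D791",
    SchemaClass.COMPLEX: "#ABD1E3",
    SchemaClass.ENTITY_SET: "#A0BBCD",
    SchemaClass.GENE: "#F7E28D",
    SchemaClass.RNA: "#DEC4E8",
    SchemaClass.PROCESS_NODE: "#C9C9C9",
}

_FILLS_STANDARD = {
    SchemaClass.PROTEIN: "#CCFFCC",
    SchemaClass.CHEMICAL: "#B3DE69",
    SchemaClass.COMPLEX: "#CCFFFF",
    SchemaClass.ENTITY_SET: "#CCCCFF",
    SchemaClass.GENE: "#FFFFCC",
    SchemaClass.RNA: "#FFCCFF",
    SchemaClass.PROCESS_NODE: "#E0E0E0",
}

_PALETTE = (
    "#E415A560",
    "#1F77B460",
    "#2CA02C60",
    "#FF7F0E60",
    "#9467BD60",
    "#8C564B60",
    "#17BECF60",
    "#BCBD2260",
)

MODERN = ColorProfile(
    name="modern",
    node_fill=dict(_FILLS_MODERN),
    node_stroke={k: "#545454" for k in SchemaClass},
    subpathway_palette=_PALETTE,
    overlay_gradient=("#FFFF33", "#FF6600"),
    not_significant_color="#C8C8C8",
    hit_bar_color="#FFD700",
)

STANDARD = ColorProfile(
    name="standard",
    node_fill=dict(_FILLS_STANDARD),
    node_stroke={k: "#000000" for k in SchemaClass},
    subpathway_palette=_PALETTE,
    overlay_gradient=("#FFFFE0", "#FF4500"),
    not_significant_color="#B0B0B0",
    hit_bar_color="#FFD700",
)

PROFILES: dict[str, ColorProfile] = {"modern": MODERN, "standard": STANDARD}


def get_profile(name: str) -> ColorProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown colour profile '{name}' (available: {sorted(PROFILES)})"
        ) from None
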