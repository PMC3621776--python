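"""Deterministic SVG rendering of a Collier de Perles layout.

Conventions follow the standard display: one bead per IMGT slot (circles,
squares for the six anchors), the residue letter centred in the bead, the
five conserved positions in red bold letters, CDR loop beads accented red /
orange / purple for CDR1/2/3, differences from a reference outlined in
pink, and backbone hydrogen bonds as green lines under the beads.  Gap
slots are empty outlined beads.

Output is byte-deterministic: fixed element order (display order), fixed
attribute order, two-decimal coordinates, no timestamps or generator
metadata — identical inputs give identical bytes, which makes golden-file
testing possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import numbering, properties
from .errors import CollierError
from .gapper import Difference, GappedDomain
from .layout import Layout
from .numbering import ImgtPosition
from .profile import Profile, dominant_class, hydrophobic_positions
from .structure import HBond

__all__ = ["RenderStyle", "render_svg", "MODES"]

MODES = ("hydropathy", "volume", "physicochemical", "profile50", "profile80")

_HYDROPATHY_COLORS = {
    "hydrophobic": "blue",
    "neutral": "#b8d4e8",
    "hydrophilic": "#f2f2f2",
}
_VOLUME_COLORS = {
    "very_small": "#ffffcc",
    "small": "#c2e699",
    "medium": "#78c679",
    "large": "#31a354",
    "very_large": "#006837",
}
_PHYSICOCHEMICAL_COLORS = {
    "aliphatic": "#80b1d3",
    "cysteine": "#ffed6f",
    "acidic": "#fb8072",
    "aromatic": "#bc80bd",
    "glycine": "#d9d9d9",
    "histidine": "#fccde5",
    "basic": "#8dd3c7",
    "methionine": "#ffffb3",
    "amide": "#bebada",
    "proline": "#fdb462",
    "hydroxyl": "#b3de69",
}


@dataclass(frozen=True)
class RenderStyle:
    """Colors and shapes; only the documented conventions are contractual."""

    mode: str = "hydropathy"
    profile_dimension: str = "hydropathy"  # dimension used by profile80
    hydrophobic_threshold: float = 0.5
    dominant_threshold: float = 0.8
    hydropathy_colors: dict = field(default_factory=lambda: dict(_HYDROPATHY_COLORS))
    volume_colors: dict = field(default_factory=lambda: dict(_VOLUME_COLORS))
    physicochemical_colors: dict = field(
        default_factory=lambda: dict(_PHYSICOCHEMICAL_COLORS)
    )
    cdr_colors: dict = field(
        default_factory=lambda: {"CDR1": "red", "CDR2": "orange", "CDR3": "purple"}
    )
    default_fill: str = "white"
    gap_stroke: str = "#999999"
    bead_stroke: str = "#333333"
    conserved_text_color: str = "red"
    difference_border: str = "pink"
    hbond_color: str = "green"
    back_layer_opacity: float = 0.55

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown plot mode {self.mode!r}; choose from {MODES}")

    def class_colors(self, dimension: str) -> dict:
        return {
            "hydropathy": self.hydropathy_colors,
            "volume": self.volume_colors,
            "physicochemical": self.physicochemical_colors,
        }[dimension]


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _bead_fill(
    pos: ImgtPosition,
    residue: str | None,
    style: RenderStyle,
    profile: Profile | None,
    hydset: frozenset | None,
) -> str:
    if style.mode == "profile50":
        return "blue" if pos in hydset else style.default_fill
    if style.mode == "profile80":
        cls = dominant_class(
            profile, pos, style.profile_dimension, style.dominant_threshold
        )
        return style.class_colors(style.profile_dimension).get(cls, style.default_fill)
    if residue is None:
        return "none"
    try:
        assign = properties.classify(residue)
    except properties.UnclassifiableResidue:
        return style.default_fill
    return style.class_colors(style.mode)[assign.class_in(style.mode)]


def render_svg(
    layout: Layout,
    g: GappedDomain,
    style: RenderStyle | None = None,
    profile: Profile | None = None,
    differences: list[Difference] | None = None,
    hbonds: list[HBond] | None = None,
) -> str:
    """Render a gapped domain on a layout as an SVG 1.1 document string."""
    style = style or RenderStyle()
    if style.mode in ("profile50", "profile80") and profile is None:
        raise ValueError(f"mode {style.mode!r} requires a statistical profile")
    if set(g.slots) - set(layout.points):
        raise CollierError("layout does not cover every slot of the domain")

    geom = layout.geometry
    sc, m = geom.scale, geom.margin
    xs = [pt.x for pt in layout.points.values()]
    ys = [pt.y for pt in layout.points.values()]
    w = (max(xs) - min(xs) + 2 * m) * sc
    h = (max(ys) - min(ys) + 2 * m) * sc
    x0, ytop = min(xs), max(ys)

    def sx(x: float) -> float:
        return (x - x0 + m) * sc

    def sy(y: float) -> float:
        return (ytop - y + m) * sc  # flip: abstract y grows upward

    r = geom.bead_radius * sc
    diffset = {d.position for d in differences} if differences else set()
    hydset = (
        hydrophobic_positions(profile, style.hydrophobic_threshold)
        if style.mode == "profile50" and profile is not None
        else frozenset()
    )

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
    ]

    # hydrogen bonds first so beads draw over the line ends
    for b in hbonds or []:
        if b.donor not in layout.points or b.acceptor not in layout.points:
            continue
        p, q = layout.points[b.donor], layout.points[b.acceptor]
        out.append(
            f'<line class="hbond" x1="{_fmt(sx(p.x))}" y1="{_fmt(sy(p.y))}" '
            f'x2="{_fmt(sx(q.x))}" y2="{_fmt(sy(q.y))}" '
            f'stroke="{style.hbond_color}" stroke-width="2.00"/>'
        )

    anchors = numbering.ANCHORS
    conserved = set(numbering.CONSERVED)
    # back layer first so the front layer draws on top
    order = sorted(
        layout.points, key=lambda p: (layout.points[p].layer != "back", p)
    )
    for pos in order:
        pt = layout.points[pos]
        residue = g.slots.get(pos)
        fill = _bead_fill(pos, residue, style, profile, hydset)
        if pos in diffset:
            stroke, swidth = style.difference_border, 3.0
        elif residue is None:
            stroke, swidth = style.gap_stroke, 1.0
        elif pt.block in style.cdr_colors:
            stroke, swidth = style.cdr_colors[pt.block], 2.0
        else:
            stroke, swidth = style.bead_stroke, 1.0
        opacity = style.back_layer_opacity if pt.layer == "back" else 1.0
        common = (
            f'fill="{fill}" stroke="{stroke}" stroke-width="{_fmt(swidth)}" '
            f'opacity="{_fmt(opacity)}"'
        )
        cx, cy = sx(pt.x), sy(pt.y)
        if pos.number in anchors and pos.insertion == 0:
            out.append(
                f'<rect class="bead anchor" x="{_fmt(cx - r)}" y="{_fmt(cy - r)}" '
                f'width="{_fmt(2 * r)}" height="{_fmt(2 * r)}" {common}/>'
            )
        else:
            out.append(
                f'<circle class="bead" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                f'r="{_fmt(r)}" {common}/>'
            )
        if residue is not None:
            is_cons = pos.number in conserved and pos.insertion == 0
            color = style.conserved_text_color if is_cons else "black"
            weight = "bold" if is_cons else "normal"
            out.append(
                f'<text class="label" x="{_fmt(cx)}" y="{_fmt(cy)}" '
                f'text-anchor="middle" dominant-baseline="central" '
                f'font-family="monospace" font-size="{_fmt(r)}" '
                f'font-weight="{weight}" fill="{color}">{residue}</text>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"
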