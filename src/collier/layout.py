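"""2D bead coordinates for one-layer and two-layer Collier de Perles.

The nine framework beta strands are drawn as vertical columns traversed in
serpentine fashion (even columns downward, odd columns upward, bottoms on a
common baseline), and the three CDR loops as arcs over the gap between the
strands they connect.  Loop arcs always carry the full region capacity of
beads (plus CDR3 insertions), so gapped slots appear as empty beads at the
top of the loop.

In the two-layer view each strand belongs to one of the two beta sheets
([A,B,E,D] in front, [G,F,C,C',C''] in back by default, matching the V
domain sandwich); the back layer is drawn with a small diagonal offset.
Coordinates are abstract units (1.0 = bead spacing); rendering applies the
pixel scale.  Aesthetics are configurable and explicitly not part of
correctness: the contract is unique coordinates, full slot coverage, nine
strand blocks, three loop blocks and bounded steps between consecutive
positions within a layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

from . import numbering
from .errors import ConfigurationError
from .gapper import GappedDomain
from .numbering import ImgtPosition

__all__ = [
    "GeometryConfig",
    "Strand",
    "LayoutPoint",
    "Layout",
    "load_strand_table",
    "layout_one_layer",
    "layout_two_layers",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry constants, in bead-spacing units unless noted."""

    spacing: float = 1.0          # distance between successive strand beads
    bead_radius: float = 0.35
    arc_height_per_bead: float = 0.6  # loop arc rise per loop bead (+1)
    max_step: float = 3.0         # contract: consecutive same-layer step bound
    layer_dx: float = 0.45        # back-layer diagonal offset
    layer_dy: float = 0.45
    scale: float = 40.0           # px per unit when rendering
    margin: float = 2.0           # units of padding when rendering

    @classmethod
    def from_file(cls, path) -> "GeometryConfig":
        """Read ``key = value`` lines; unknown keys are a configuration error."""
        values = {}
        fields = {f.name for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"line {lineno}: expected key = value")
                key, _, value = (s.strip() for s in line.partition("="))
                if key not in fields:
                    raise ConfigurationError(f"line {lineno}: unknown geometry key {key!r}")
                values[key] = float(value)
        return replace(cls(), **values)


@dataclass(frozen=True)
class Strand:
    name: str
    start: int
    end: int
    one_layer_col: int
    sheet: str  # "front" | "back"
    two_layer_col: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def load_strand_table(source: str | None = None) -> list[Strand]:
    if source is None:
        source = resources.files("collier.data").joinpath("strands.tsv").read_text()
    strands: list[Strand] = []
    for lineno, raw in enumerate(source.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split("\t")
        if len(f) != 6:
            raise ConfigurationError(f"strand table line {lineno}: expected 6 fields")
        if f[4] not in ("front", "back"):
            raise ConfigurationError(f"strand table line {lineno}: bad sheet {f[4]!r}")
        strands.append(Strand(f[0], int(f[1]), int(f[2]), int(f[3]), f[4], int(f[5])))
    if len(strands) != 9:
        raise ConfigurationError(f"expected 9 strands, got {len(strands)}")
    covered = sorted(n for s in strands for n in range(s.start, s.end + 1))
    fr_positions = sorted(
        n
        for label, (lo, hi) in numbering.REGIONS.items()
        if label.startswith("FR")
        for n in range(lo, hi + 1)
    )
    if covered != fr_positions:
        raise ConfigurationError("strand table does not tile the framework regions")
    return strands


_LOOPS = (  # loop label, region, preceding strand, following strand
    ("CDR1", "CDR1-IMGT", "B", "C"),
    ("CDR2", "CDR2-IMGT", "C'", "C''"),
    ("CDR3", "CDR3-IMGT", "F", "G"),
)


@dataclass(frozen=True)
class LayoutPoint:
    x: float
    y: float
    layer: str  # "single" | "front" | "back"
    block: str  # strand name or CDR label


@dataclass
class Layout:
    points: dict[ImgtPosition, LayoutPoint]
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def blocks(self) -> set[str]:
        return {pt.block for pt in self.points.values()}

    def strand_blocks(self) -> set[str]:
        return {b for b in self.blocks() if not b.startswith("CDR")}

    def loop_blocks(self) -> set[str]:
        return {b for b in self.blocks() if b.startswith("CDR")}


def _strand_coords(
    strand: Strand, col: int, layer: str, geom: GeometryConfig, offset: tuple[float, float]
) -> dict[ImgtPosition, LayoutPoint]:
    """Vertical column; even columns run downward (first bead at top)."""
    sp = geom.spacing
    x = col * sp + offset[0]
    n = strand.length
    pts = {}
    for i, num in enumerate(range(strand.start, strand.end + 1)):
        y = ((n - 1 - i) if col % 2 == 0 else i) * sp + offset[1]
        pts[ImgtPosition(num)] = LayoutPoint(x, y, layer, strand.name)
    return pts


def _loop_coords(
    label: str,
    slots: list[ImgtPosition],
    p1: LayoutPoint,
    p2: LayoutPoint,
    layer: str,
    geom: GeometryConfig,
) -> dict[ImgtPosition, LayoutPoint]:
    """Beads along a quadratic Bezier arcing above the flanking strand tops."""
    n = len(slots)
    h = geom.arc_height_per_bead * (n + 1) * geom.spacing
    cx, cy = (p1.x + p2.x) / 2.0, max(p1.y, p2.y) + h
    pts = {}
    for i, pos in enumerate(slots, start=1):
        t = i / (n + 1)
        x = (1 - t) ** 2 * p1.x + 2 * (1 - t) * t * cx + t**2 * p2.x
        y = (1 - t) ** 2 * p1.y + 2 * (1 - t) * t * cy + t**2 * p2.y
        pts[pos] = LayoutPoint(x, y, layer, label)
    return pts


def _build(
    g: GappedDomain,
    geom: GeometryConfig,
    strands: list[Strand],
    two_layers: bool,
) -> Layout:
    by_name = {s.name: s for s in strands}
    points: dict[ImgtPosition, LayoutPoint] = {}
    for s in strands:
        if two_layers:
            layer = s.sheet
            col = s.two_layer_col
            offset = (geom.layer_dx, geom.layer_dy) if s.sheet == "back" else (0.0, 0.0)
        else:
            layer, col, offset = "single", s.one_layer_col, (0.0, 0.0)
        points.update(_strand_coords(s, col, layer, geom, offset))
    for label, region, before, after in _LOOPS:
        length = g.region_length(region)
        slots = numbering.cdr_slots(region, length)
        p1 = points[ImgtPosition(by_name[before].end)]
        p2 = points[ImgtPosition(by_name[after].start)]
        layer = p1.layer  # loop drawn with its preceding strand's layer
        points.update(_loop_coords(label, slots, p1, p2, layer, geom))
    missing = [p for p in g.slots if p not in points]
    if missing:  # defensive: every slot must get coordinates
        raise AssertionError(f"unplaced slots: {missing}")
    return Layout(points={p: points[p] for p in sorted(points)}, geometry=geom)


def layout_one_layer(
    g: GappedDomain,
    geometry: GeometryConfig | None = None,
    strands: list[Strand] | None = None,
) -> Layout:
    """Single-layer Collier de Perles coordinates for a gapped domain."""
    return _build(g, geometry or GeometryConfig(), strands or load_strand_table(), False)


def layout_two_layers(
    g: GappedDomain,
    geometry: GeometryConfig | None = None,
    strands: list[Strand] | None = None,
) -> Layout:
    """Two-layer coordinates: each strand on its beta sheet (front or back)."""
    return _build(g, geometry or GeometryConfig(), strands or load_strand_table(), True)
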