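"""IMGT unique numbering for V domains.

A V domain occupies positions 1-128 tiled into seven regions:

====== ========= ========
region positions capacity
====== ========= ========
FR1      1-26      26
CDR1    27-38      12
FR2     39-55      17
CDR2    56-65      10
FR3     66-104     39
CDR3   105-117     13
FR4    118-128     11
====== ========= ========

A sequence whose CDR is shorter than the region capacity leaves positions
empty ("gaps at the top of the loop"): the occupied positions are the first
ceil(L/2) and the last floor(L/2) of the region.  CDR3 loops longer than 13
gain insertion positions 111.1, 111.2, ... and 112.2, 112.1 between 111
and 112.

Five conserved positions characterise every V domain (23 1st-CYS,
41 CONSERVED-TRP, 89 hydrophobic, 104 2nd-CYS, 118 J-PHE or J-TRP) and six
framework anchors (26, 39, 55, 66, 104, 118) flank the three CDR loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering

__all__ = [
    "ImgtPosition",
    "VScheme",
    "scheme_constants",
    "region_of",
    "gap_positions",
    "extra_positions",
    "cdr_slots",
    "MAX_CDR3_INSERTIONS",
]

#: ordered region table: label -> (first, last) inclusive
REGIONS: dict[str, tuple[int, int]] = {
    "FR1-IMGT": (1, 26),
    "CDR1-IMGT": (27, 38),
    "FR2-IMGT": (39, 55),
    "CDR2-IMGT": (56, 65),
    "FR3-IMGT": (66, 104),
    "CDR3-IMGT": (105, 117),
    "FR4-IMGT": (118, 128),
}

CONSERVED: dict[int, str] = {
    23: "1st-CYS",
    41: "CONSERVED-TRP",
    89: "hydrophobic",
    104: "2nd-CYS",
    118: "J-PHE-or-J-TRP",
}

ANCHORS: frozenset[int] = frozenset({26, 39, 55, 66, 104, 118})

#: default ceiling on CDR3 insertion positions (lengths up to 13 + 20)
MAX_CDR3_INSERTIONS = 20


@total_ordering
@dataclass(frozen=True)
class ImgtPosition:
    """A numbered slot of the scheme, e.g. ``104`` or the insertion ``111.2``.

    Insertions exist only on 111 and 112 (long CDR3).  Display order runs
    105 ... 111, 111.1, ..., 111.k, 112.m, ..., 112.1, 112, 113 ... 117,
    i.e. the 112.x series counts *down* toward 112.
    """

    number: int
    insertion: int = 0

    def __post_init__(self):
        if not 1 <= self.number <= 128:
            raise ValueError(f"IMGT position out of range 1-128: {self.number}")
        if self.insertion and self.number not in (111, 112):
            raise ValueError(
                f"insertion suffix only allowed on 111/112, got {self}"
            )
        if self.insertion < 0:
            raise ValueError("insertion suffix must be >= 1")

    def _key(self) -> tuple[int, int]:
        # 112.x sorts before bare 112 and descends with x
        if self.number == 112:
            return (112, -self.insertion)
        return (self.number, self.insertion)

    def __lt__(self, other: "ImgtPosition") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.number}.{self.insertion}" if self.insertion else str(self.number)

    @classmethod
    def parse(cls, label: str) -> "ImgtPosition":
        if "." in label:
            n, i = label.split(".", 1)
            return cls(int(n), int(i))
        return cls(int(label))


@dataclass(frozen=True)
class VScheme:
    """The constant V-domain scheme (regions, conserved positions, anchors)."""

    regions: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(REGIONS))
    conserved: dict[int, str] = field(default_factory=lambda: dict(CONSERVED))
    anchors: frozenset[int] = ANCHORS

    @property
    def cdr_capacities(self) -> dict[str, int]:
        return {
            r: hi - lo + 1 for r, (lo, hi) in self.regions.items() if r.startswith("CDR")
        }


def scheme_constants() -> VScheme:
    """Return the constant scheme."""
    return VScheme()


def region_of(p: ImgtPosition | int) -> str:
    """Region label (``FR1-IMGT`` ... ``FR4-IMGT``) of a position."""
    if isinstance(p, int):
        p = ImgtPosition(p)
    for label, (lo, hi) in REGIONS.items():
        if lo <= p.number <= hi:
            return label
    raise ValueError(f"position {p} outside 1-128")  # unreachable: ctor checks


def _region_range(region: str) -> tuple[int, int]:
    label = region if region.endswith("-IMGT") else region + "-IMGT"
    try:
        lo, hi = REGIONS[label]
    except KeyError:
        raise ValueError(f"unknown region {region!r}") from None
    return lo, hi


def gap_positions(region: str, observed_length: int) -> frozenset[ImgtPosition]:
    """Positions of a CDR left empty for an observed loop length.

    The occupied positions are the first ceil(L/2) and last floor(L/2)
    positions of the region; the remainder — the top of the loop — is
    gapped.  For CDR3 lengths above capacity use :func:`extra_positions`.
    """
    lo, hi = _region_range(region)
    if not region.split("-")[0].upper().startswith("CDR"):
        raise ValueError(f"{region!r} is not a CDR region")
    cap = hi - lo + 1
    if observed_length < 0 or observed_length > cap:
        raise ValueError(
            f"length {observed_length} outside 0..{cap} for {region}"
        )
    head = (observed_length + 1) // 2
    tail = observed_length // 2
    occupied = set(range(lo, lo + head)) | set(range(hi - tail + 1, hi + 1))
    return frozenset(ImgtPosition(n) for n in range(lo, hi + 1) if n not in occupied)


def extra_positions(cdr3_length: int, maximum: int = 13 + MAX_CDR3_INSERTIONS) -> list[ImgtPosition]:
    """Insertion positions for a CDR3 longer than 13, in order of addition.

    The series alternates 112.1, 111.1, 112.2, 111.2, ...; display order is
    handled by :class:`ImgtPosition` ordering.
    """
    if cdr3_length <= 13:
        raise ValueError(f"CDR3 length {cdr3_length} needs no insertion positions")
    if cdr3_length > maximum:
        raise ValueError(f"CDR3 length {cdr3_length} above configured maximum {maximum}")
    out: list[ImgtPosition] = []
    for k in range(cdr3_length - 13):
        base = 112 if k % 2 == 0 else 111
        out.append(ImgtPosition(base, k // 2 + 1))
    return out


def cdr_slots(region: str, observed_length: int) -> list[ImgtPosition]:
    """All slots of a CDR region in display order, including insertions.

    For lengths within capacity this is simply the region's positions; a
    long CDR3 additionally carries its insertion positions.
    """
    lo, hi = _region_range(region)
    base = [ImgtPosition(n) for n in range(lo, hi + 1)]
    if region.startswith("CDR3") and observed_length > 13:
        base.extend(extra_positions(observed_length))
    return sorted(base)
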