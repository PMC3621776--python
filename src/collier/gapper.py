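"""Gapping of ungapped V-domain sequences onto IMGT positions.

The gapper is motif-based: it anchors the sequence on the four conserved
framework residues (1st-CYS 23, CONSERVED-TRP 41, 2nd-CYS 104, J-PHE or
J-TRP 118), which pin down the framework lengths, and derives the three
CDR loop lengths from the spacing between anchors.  Gaps within each CDR
are then placed at the top of the loop by :func:`collier.numbering.gap_positions`.

Framework regions are assumed at full capacity, with one exception: the two
standard germline framework gaps of expressed human V domains — position 10
in FR1 and position 73 in FR3 — are recognised.  Full-capacity frameworks
are preferred; when FR1 requires the position-10 gap (a germline-style
sequence) the position-73 FR3 gap is preferred over a full FR3, since the
two patterns co-occur in expressed human V genes.  Any other framework
deletion must be supplied as pre-gapped input (:func:`parse_gapped`).

Conserved-slot mismatches (e.g. no hydrophobic residue at 89) are warnings
by default so that engineered domains still render; ``strict=True`` turns
them into errors.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import numbering, properties
from .errors import NotNumberableError
from .numbering import ImgtPosition

__all__ = [
    "GappedDomain",
    "AnchorHits",
    "Difference",
    "LengthDifference",
    "ComparisonResult",
    "detect_anchors",
    "gap_sequence",
    "parse_gapped",
    "ungap",
    "compare_to_reference",
    "pick_closest_reference",
    "synthesize_domain",
]

GAP = "."

# framework capacities (FR2 has no supported germline gap)
FR1_FULL, FR2_LEN, FR3_FULL, FR4_LEN = 26, 17, 39, 11
FR1_GAP_POSITION, FR3_GAP_POSITION = 10, 73


@dataclass(frozen=True)
class AnchorHits:
    """0-based indices of the conserved anchors in the ungapped sequence."""

    cys23: int
    trp41: int
    cys104: int
    j118: int
    fr1_length: int
    fr3_length: int
    cdr_lengths: tuple[int, int, int]
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        idx = (self.cys23, self.trp41, self.cys104, self.j118)
        if list(idx) != sorted(set(idx)):
            raise ValueError("anchor indices must be strictly increasing")


@dataclass
class GappedDomain:
    """A V domain laid onto the 128 scheme slots (plus CDR3 insertions).

    ``slots`` maps every position, in display order, to a residue or None
    (gap).  Dropping the gaps reproduces the input sequence exactly.
    """

    slots: dict[ImgtPosition, str | None]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.slots = dict(sorted(self.slots.items()))

    # -- accessors ---------------------------------------------------------
    def residue(self, p: ImgtPosition | int) -> str | None:
        if isinstance(p, int):
            p = ImgtPosition(p)
        return self.slots.get(p)

    def occupied(self) -> list[ImgtPosition]:
        return [p for p, r in self.slots.items() if r is not None]

    def gaps(self) -> list[ImgtPosition]:
        return [p for p, r in self.slots.items() if r is None]

    def region_length(self, region: str) -> int:
        return sum(
            1
            for p, r in self.slots.items()
            if r is not None and numbering.region_of(p) == region
        )

    @property
    def cdr_lengths(self) -> tuple[int, int, int]:
        return (
            self.region_length("CDR1-IMGT"),
            self.region_length("CDR2-IMGT"),
            self.region_length("CDR3-IMGT"),
        )

    def gapped_sequence(self) -> str:
        return "".join(r if r is not None else GAP for r in self.slots.values())

    def ungapped(self) -> str:
        return "".join(r for r in self.slots.values() if r is not None)


def _clean(seq: str) -> str:
    return seq.strip().upper().replace("-", GAP)


def detect_anchors(
    seq: str, min_length: int = 85, max_length: int = 140
) -> AnchorHits:
    """Locate the conserved-framework anchors in an ungapped sequence.

    Candidate framework lengths are tried in preference order (full first)
    and the first assignment consistent with all four anchors and the CDR
    capacities wins.  Raises :class:`NotNumberableError` naming the first
    anchor that could not be placed.
    """
    s = _clean(seq).replace(GAP, "")
    n = len(s)
    if not min_length <= n <= max_length:
        raise NotNumberableError(
            f"sequence length {n} outside V-domain bounds {min_length}-{max_length}"
        )
    furthest = "1st-CYS"
    for f1 in (FR1_FULL, FR1_FULL - 1):
        i1 = f1 - 4  # 1st-CYS at position 23, three FR1 residues follow it
        if i1 >= n or s[i1] != "C":
            continue
        furthest = max(furthest, "CONSERVED-TRP", key=_anchor_rank)
        for a in range(0, 13):
            iw = f1 + a + 2  # CONSERVED-TRP is the 3rd residue of FR2
            if iw >= n or s[iw] != "W":
                continue
            furthest = max(furthest, "2nd-CYS", key=_anchor_rank)
            fr3_order = (FR3_FULL, FR3_FULL - 1) if f1 == FR1_FULL else (FR3_FULL - 1, FR3_FULL)
            for f3 in fr3_order:
                for b in range(0, 11):
                    i2 = f1 + a + FR2_LEN + b + f3 - 1
                    if i2 >= n or s[i2] != "C":
                        continue
                    furthest = max(furthest, "J-PHE-or-J-TRP", key=_anchor_rank)
                    c = n - (i2 + 1) - FR4_LEN
                    if c < 0 or c > 13 + numbering.MAX_CDR3_INSERTIONS:
                        continue
                    ij = i2 + 1 + c
                    if s[ij] not in "FW":
                        continue
                    notes = []
                    if f1 < FR1_FULL:
                        notes.append(f"FR1 germline gap at position {FR1_GAP_POSITION}")
                    if f3 < FR3_FULL:
                        notes.append(f"FR3 germline gap at position {FR3_GAP_POSITION}")
                    return AnchorHits(
                        cys23=i1,
                        trp41=iw,
                        cys104=i2,
                        j118=ij,
                        fr1_length=f1,
                        fr3_length=f3,
                        cdr_lengths=(a, b, c),
                        notes=tuple(notes),
                    )
    raise NotNumberableError(
        f"not a numberable V domain: no consistent placement for {furthest}",
        anchor=furthest,
    )


_ANCHOR_ORDER = ["1st-CYS", "CONSERVED-TRP", "2nd-CYS", "J-PHE-or-J-TRP"]


def _anchor_rank(name: str) -> int:
    return _ANCHOR_ORDER.index(name)


def _fr_positions(region: str, length: int) -> list[ImgtPosition]:
    lo, hi = numbering.REGIONS[region]
    nums = list(range(lo, hi + 1))
    if region == "FR1-IMGT" and length == FR1_FULL - 1:
        nums.remove(FR1_GAP_POSITION)
    elif region == "FR3-IMGT" and length == FR3_FULL - 1:
        nums.remove(FR3_GAP_POSITION)
    elif length != len(nums):
        raise ValueError(f"unsupported {region} length {length}")
    return [ImgtPosition(k) for k in nums]


def gap_sequence(seq: str, strict: bool = False) -> GappedDomain:
    """Gap an ungapped V-domain sequence according to the unique numbering."""
    s = _clean(seq).replace(GAP, "")
    hits = detect_anchors(s)
    a, b, c = hits.cdr_lengths

    slots: dict[ImgtPosition, str | None] = {
        ImgtPosition(k): None for k in range(1, 129)
    }
    cursor = 0

    def fill(posns: list[ImgtPosition]):
        nonlocal cursor
        for p in posns:
            slots[p] = s[cursor]
            cursor += 1

    for region, length in (
        ("FR1-IMGT", hits.fr1_length),
        ("CDR1-IMGT", a),
        ("FR2-IMGT", FR2_LEN),
        ("CDR2-IMGT", b),
        ("FR3-IMGT", hits.fr3_length),
        ("CDR3-IMGT", c),
        ("FR4-IMGT", FR4_LEN),
    ):
        if region.startswith("CDR"):
            all_slots = numbering.cdr_slots(region, length)
            for p in all_slots:
                slots.setdefault(p, None)
            if length <= numbering.REGIONS[region][1] - numbering.REGIONS[region][0] + 1:
                gapped = numbering.gap_positions(region, min(length, 13 if region == "CDR3-IMGT" else length))
                occupied = [p for p in all_slots if p not in gapped]
            else:
                occupied = all_slots  # long CDR3: every slot incl. insertions
            fill(occupied)
        else:
            fill(_fr_positions(region, length))

    domain = GappedDomain(slots=slots)
    domain.warnings.extend(hits.notes)
    _check_conserved(domain, strict)
    return domain


def _check_conserved(domain: GappedDomain, strict: bool) -> None:
    checks = {
        23: lambda r: r == "C",
        41: lambda r: r == "W",
        89: lambda r: _is_hydrophobic(r),
        104: lambda r: r == "C",
        118: lambda r: r in "FW",
    }
    for pos, ok in checks.items():
        r = domain.residue(pos)
        if r is None or not ok(r):
            msg = (
                f"conserved position {pos} ({numbering.CONSERVED[pos]}): "
                f"found {r or 'gap'}"
            )
            if strict:
                raise NotNumberableError(msg, anchor=numbering.CONSERVED[pos])
            domain.warnings.append(msg)


def _is_hydrophobic(r: str) -> bool:
    try:
        return properties.classify(r).hydropathy_class == "hydrophobic"
    except properties.UnclassifiableResidue:
        return False


def parse_gapped(gapped: str, strict: bool = False) -> GappedDomain:
    """Build a domain from a pre-gapped 128-column sequence ('.' or '-' gaps).

    Arbitrary gap patterns (including framework gaps beyond the two germline
    ones) are accepted; CDR3 insertion columns are not representable here.
    """
    s = _clean(gapped)
    if len(s) != 128:
        raise ValueError(f"pre-gapped V-domain input must have 128 columns, got {len(s)}")
    slots = {
        ImgtPosition(k): (None if ch == GAP else ch)
        for k, ch in enumerate(s, start=1)
    }
    domain = GappedDomain(slots=slots)
    _check_conserved(domain, strict)
    return domain


def ungap(domain: GappedDomain) -> str:
    """Concatenate residues in display order, dropping gaps."""
    return domain.ungapped()


@dataclass(frozen=True)
class Difference:
    """Substitution at a co-occupied position relative to a reference."""

    position: ImgtPosition
    query: str
    reference: str
    change: properties.ChangeCharacteristics | None

    def __post_init__(self):
        if self.query == self.reference:
            raise ValueError("Difference requires differing residues")


@dataclass(frozen=True)
class LengthDifference:
    """Position occupied in exactly one of query/reference."""

    position: ImgtPosition
    query: str | None
    reference: str | None


@dataclass
class ComparisonResult:
    differences: list[Difference]
    length_differences: list[LengthDifference]


def compare_to_reference(
    query: GappedDomain,
    reference: GappedDomain,
    table: properties.ClassificationTable | None = None,
) -> ComparisonResult:
    """Positional differences between a query and a reference domain."""
    diffs: list[Difference] = []
    lendiffs: list[LengthDifference] = []
    for p in sorted(set(query.slots) | set(reference.slots)):
        q, r = query.slots.get(p), reference.slots.get(p)
        if q is not None and r is not None:
            if q != r:
                try:
                    change = properties.compare_residues(q, r, table)
                except properties.UnclassifiableResidue:
                    change = None
                diffs.append(Difference(p, q, r, change))
        elif q is not None or r is not None:
            lendiffs.append(LengthDifference(p, q, r))
    return ComparisonResult(diffs, lendiffs)


def pick_closest_reference(
    query: GappedDomain, directory: list[tuple[str, GappedDomain]]
) -> tuple[str, GappedDomain, float]:
    """Directory entry maximising position-wise identity over co-occupied slots.

    Ties break toward the earlier directory entry.  Identity is the fraction
    of co-occupied positions with equal residues (0.0 when none co-occupied).
    """
    if not directory:
        raise ValueError("empty reference directory")
    best: tuple[str, GappedDomain, float] | None = None
    for name, ref in directory:
        shared = [
            p
            for p in query.slots
            if query.slots[p] is not None and ref.slots.get(p) is not None
        ]
        matches = sum(1 for p in shared if query.slots[p] == ref.slots[p])
        ident = matches / len(shared) if shared else 0.0
        if best is None or ident > best[2]:
            best = (name, ref, ident)
    return best


# residues drawn for non-conserved positions of synthetic fixtures: the 18
# standard codes minus C and W, so the conserved motifs stay unambiguous
_FIXTURE_ALPHABET = "ADEFGHIKLMNPQRSTVY"
_HYDROPHOBIC_CHOICES = "AVILFM"


def synthesize_domain(cdr_lengths: tuple[int, int, int], seed: int) -> str:
    """Deterministic synthetic ungapped V-domain sequence.

    Frameworks are at full capacity; C/W/C and F-or-W are placed at the
    conserved offsets (positions 23, 41, 104, 118), a hydrophobic residue
    at position 89, and all other residues are drawn uniformly from the 18
    codes excluding C and W.  Total length is 93 + a + b + c.
    """
    a, b, c = cdr_lengths
    caps = (12, 10, 13 + numbering.MAX_CDR3_INSERTIONS)
    for length, cap, name in zip(cdr_lengths, caps, ("CDR1", "CDR2", "CDR3")):
        if not 0 <= length <= cap:
            raise ValueError(f"{name} length {length} outside 0..{cap}")
    rng = random.Random(seed)

    def rand(k: int) -> list[str]:
        return [rng.choice(_FIXTURE_ALPHABET) for _ in range(k)]

    fr1 = rand(22) + ["C"] + rand(3)                      # C at position 23
    fr2 = rand(2) + ["W"] + rand(14)                      # W at position 41
    fr3 = rand(23) + [rng.choice(_HYDROPHOBIC_CHOICES)] + rand(14) + ["C"]
    fr4 = [rng.choice("FW")] + rand(10)                   # J-PHE/J-TRP at 118
    return "".join(fr1 + rand(a) + fr2 + rand(b) + fr3 + rand(c) + fr4)
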