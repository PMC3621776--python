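"""Per-position statistical profiles over sets of gapped domains.

A profile records, for every IMGT position, how many of the source domains
occupy it and the frequency of each property class among the residues
found there.  Frequencies are computed over the classifiable residues
occupying the position (gaps and unclassifiable codes never dilute them),
so short CDRs simply lower a position's occupancy.

Two display statistics derive from a profile, mirroring the standard plot
options: the set of positions where the hydrophobic hydropathy class
reaches a threshold fraction (default 50%, boundary inclusive — "50% or
more"), and the dominant class of a position in a given dimension at a
higher threshold (default 80%, also inclusive).
"""

from __future__ import annotations

import sys
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from . import properties
from .gapper import GappedDomain
from .numbering import ImgtPosition
from .properties import DIMENSIONS, ClassificationTable

__all__ = ["Profile", "build_profile", "hydrophobic_positions", "dominant_class",
           "write_profile_tsv", "read_profile_tsv"]


@dataclass
class Profile:
    source_count: int
    occupancy: dict[ImgtPosition, int]
    #: counts[dimension][position][class name] -> residue count
    counts: dict[str, dict[ImgtPosition, Counter]]
    table: ClassificationTable = field(default_factory=properties.default_table)

    def positions(self) -> list[ImgtPosition]:
        return sorted(self.occupancy)

    def classifiable(self, position: ImgtPosition, dimension: str = "hydropathy") -> int:
        return sum(self.counts[dimension].get(position, Counter()).values())

    def frequency(self, position: ImgtPosition, dimension: str, cls: str) -> float:
        """Fraction of classifiable residues at ``position`` in ``cls``."""
        if dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        counter = self.counts[dimension].get(position, Counter())
        total = sum(counter.values())
        return counter[cls] / total if total else 0.0


def build_profile(
    domains: Iterable[GappedDomain], table: ClassificationTable | None = None
) -> Profile:
    """Accumulate class counts per position over a non-empty set of domains."""
    domains = list(domains)
    if not domains:
        raise ValueError("cannot build a profile from an empty domain list")
    table = table or properties.default_table()
    occupancy: dict[ImgtPosition, int] = defaultdict(int)
    counts: dict[str, dict[ImgtPosition, Counter]] = {
        d: defaultdict(Counter) for d in DIMENSIONS
    }
    for dom in domains:
        for pos, res in dom.slots.items():
            if res is None:
                continue
            occupancy[pos] += 1
            try:
                assign = properties.classify(res, table)
            except properties.UnclassifiableResidue:
                continue  # counted in occupancy, excluded from frequencies
            for dim in DIMENSIONS:
                counts[dim][pos][assign.class_in(dim)] += 1
    return Profile(
        source_count=len(domains),
        occupancy=dict(occupancy),
        counts={d: dict(c) for d, c in counts.items()},
        table=table,
    )


def hydrophobic_positions(
    profile: Profile, threshold: float = 0.5
) -> frozenset[ImgtPosition]:
    """Positions where the hydrophobic class reaches ``threshold`` (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return frozenset(
        p
        for p in profile.positions()
        if profile.classifiable(p)
        and profile.frequency(p, "hydropathy", "hydrophobic") >= threshold
    )


def dominant_class(
    profile: Profile,
    position: ImgtPosition | int,
    dimension: str,
    threshold: float = 0.8,
) -> str | None:
    """The unique class reaching ``threshold`` at a position, else None.

    At any threshold above 0.5 at most one class can qualify.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(position, int):
        position = ImgtPosition(position)
    best: str | None = None
    for cls in profile.table.catalog(dimension):
        if profile.frequency(position, dimension, cls) >= threshold:
            if best is not None:
                return None  # only reachable at thresholds <= 0.5
            best = cls
    return best


PROFILE_COLUMNS = ("position", "dimension", "class", "frequency")


def write_profile_tsv(profile: Profile, handle: TextIO | None = None) -> None:
    """One row per (position, dimension, class); occupancy rows carry counts."""
    handle = handle or sys.stdout
    handle.write(f"# sequences\t{profile.source_count}\n")
    handle.write("\t".join(PROFILE_COLUMNS) + "\n")
    for pos in profile.positions():
        handle.write(f"{pos}\toccupancy\t.\t{profile.occupancy[pos]}\n")
        for dim in DIMENSIONS:
            counter = profile.counts[dim].get(pos)
            if not counter:
                continue
            total = sum(counter.values())
            for cls in profile.table.catalog(dim):
                if counter[cls]:
                    handle.write(f"{pos}\t{dim}\t{cls}\t{counter[cls] / total:.6f}\n")


def read_profile_tsv(handle, table: ClassificationTable | None = None) -> Profile:
    """Inverse of :func:`write_profile_tsv` (frequencies re-scaled to counts)."""
    table = table or properties.default_table()
    source_count = 0
    occupancy: dict[ImgtPosition, int] = {}
    raw: dict[str, dict[ImgtPosition, dict[str, float]]] = {
        d: defaultdict(dict) for d in DIMENSIONS
    }
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("position\t"):
            continue
        if line.startswith("# sequences"):
            source_count = int(line.split("\t")[1])
            continue
        pos_s, dim, cls, value = line.split("\t")
        pos = ImgtPosition.parse(pos_s)
        if dim == "occupancy":
            occupancy[pos] = int(value)
        else:
            raw[dim][pos][cls] = float(value)
    counts: dict[str, dict[ImgtPosition, Counter]] = {d: {} for d in DIMENSIONS}
    for dim in DIMENSIONS:
        for pos, freqs in raw[dim].items():
            # recover integer counts from frequencies via the occupancy total
            total = occupancy.get(pos, 0)
            counter = Counter()
            for cls, f in freqs.items():
                counter[cls] = round(f * total)
            counts[dim][pos] = counter
    return Profile(source_count=source_count, occupancy=occupancy, counts=counts, table=table)
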