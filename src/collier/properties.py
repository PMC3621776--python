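"""Amino-acid property classes and residue-change characterisation.

The 20 standard residues are partitioned three independent ways:

* hydropathy — 3 classes (hydrophobic, neutral, hydrophilic);
* volume — 5 classes (very_small ... very_large);
* physicochemical — the 11 IMGT classes combining hydropathy, volume and
  side-chain chemistry.

Memberships are data, not code: they live in ``data/imgt_classes.tsv`` and
are validated on load.  Comparing two residues yields a boolean per
dimension plus a tier label ("identical" / "very similar" / "similar" /
"neutral" / "dissimilar" by default, configurable) used when highlighting
differences from a reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .errors import ConfigurationError, UnclassifiableResidue

__all__ = [
    "PropertyAssignment",
    "ChangeCharacteristics",
    "ClassificationTable",
    "load_class_tables",
    "classify",
    "compare_residues",
    "DEFAULT_LABEL_MAP",
]

HYDROPATHY_CLASSES = ("hydrophobic", "neutral", "hydrophilic")
VOLUME_CLASSES = ("very_small", "small", "medium", "large", "very_large")
PHYSICOCHEMICAL_CLASSES = (
    "aliphatic",
    "cysteine",
    "acidic",
    "aromatic",
    "glycine",
    "histidine",
    "basic",
    "methionine",
    "amide",
    "proline",
    "hydroxyl",
)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: tier label by number of shared dimensions; identity overrides with its own
#: label.  Replaceable via the ``label_map`` argument of compare_residues.
DEFAULT_LABEL_MAP = {
    "identity": "identical",
    3: "very similar",
    2: "similar",
    1: "neutral",
    0: "dissimilar",
}

DIMENSIONS = ("hydropathy", "volume", "physicochemical")


@dataclass(frozen=True)
class PropertyAssignment:
    residue: str
    hydropathy_class: str
    volume_class: str
    physicochemical_class: str

    def class_in(self, dimension: str) -> str:
        try:
            return getattr(self, f"{dimension}_class")
        except AttributeError:
            raise ValueError(f"unknown dimension {dimension!r}") from None


@dataclass(frozen=True)
class ChangeCharacteristics:
    residue_from: str
    residue_to: str
    same_hydropathy: bool
    same_volume: bool
    same_physicochemical: bool
    label: str


@dataclass(frozen=True)
class ClassificationTable:
    entries: dict[str, PropertyAssignment]
    hydropathy_classes: tuple[str, ...] = HYDROPATHY_CLASSES
    volume_classes: tuple[str, ...] = VOLUME_CLASSES
    physicochemical_classes: tuple[str, ...] = PHYSICOCHEMICAL_CLASSES

    def catalog(self, dimension: str) -> tuple[str, ...]:
        if dimension == "hydropathy":
            return self.hydropathy_classes
        if dimension == "volume":
            return self.volume_classes
        if dimension == "physicochemical":
            return self.physicochemical_classes
        raise ValueError(f"unknown dimension {dimension!r}")

    def members(self, dimension: str, cls: str) -> frozenset[str]:
        return frozenset(
            r for r, a in self.entries.items() if a.class_in(dimension) == cls
        )


def _parse_table(text: str) -> ClassificationTable:
    entries: dict[str, PropertyAssignment] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ConfigurationError(f"line {lineno}: expected 4 fields, got {len(fields)}")
        code, hyd, vol, chem = fields
        code = code.upper()
        if len(code) != 1 or code not in STANDARD_RESIDUES:
            raise ConfigurationError(f"line {lineno}: not a standard residue code: {code!r}")
        if code in entries:
            raise ConfigurationError(f"duplicate residue entry: {code}")
        for cls, catalog, dim in (
            (hyd, HYDROPATHY_CLASSES, "hydropathy"),
            (vol, VOLUME_CLASSES, "volume"),
            (chem, PHYSICOCHEMICAL_CLASSES, "physicochemical"),
        ):
            if cls not in catalog:
                raise ConfigurationError(
                    f"residue {code}: unknown {dim} class {cls!r}"
                )
        entries[code] = PropertyAssignment(code, hyd, vol, chem)
    missing = sorted(set(STANDARD_RESIDUES) - set(entries))
    if missing:
        raise ConfigurationError(f"missing residue entries: {', '.join(missing)}")
    return ClassificationTable(entries)


def load_class_tables(source: str | None = None) -> ClassificationTable:
    """Load and validate the classification table.

    ``source`` is the table text; by default the packaged table is used.
    Raises :class:`ConfigurationError` naming the offending entry when the
    table is malformed (missing or duplicate residue, unknown class name).
    """
    if source is None:
        source = (
            resources.files("collier.data").joinpath("imgt_classes.tsv").read_text()
        )
    return _parse_table(source)


_default_table: ClassificationTable | None = None


def default_table() -> ClassificationTable:
    global _default_table
    if _default_table is None:
        _default_table = load_class_tables()
    return _default_table


def classify(residue: str, table: ClassificationTable | None = None) -> PropertyAssignment:
    """Property assignment of a residue (case-insensitive).

    Raises :class:`UnclassifiableResidue` for anything outside the 20
    standard codes (X, B, Z, gap characters, ...) so callers can fall back
    to a default rendering style.
    """
    table = table or default_table()
    code = residue.upper()
    try:
        return table.entries[code]
    except KeyError:
        raise UnclassifiableResidue(residue) from None


def compare_residues(
    a: str,
    b: str,
    table: ClassificationTable | None = None,
    label_map: dict | None = None,
) -> ChangeCharacteristics:
    """Characterise an amino-acid change between two classifiable residues."""
    table = table or default_table()
    label_map = label_map or DEFAULT_LABEL_MAP
    pa, pb = classify(a, table), classify(b, table)
    same = tuple(pa.class_in(d) == pb.class_in(d) for d in DIMENSIONS)
    if pa.residue == pb.residue:
        label = label_map["identity"]
    else:
        label = label_map[sum(same)]
    return ChangeCharacteristics(pa.residue, pb.residue, *same, label=label)
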