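"""Collier de Perles: IMGT-style V-domain numbering, amino-acid property
classes, per-position statistical profiles and standardized 2D bead plots
for immunoglobulin / T-cell-receptor variable domains."""

from importlib import resources

from . import layout, numbering, profile, properties, render, structure
from .gapper import (
    GappedDomain,
    compare_to_reference,
    gap_sequence,
    parse_gapped,
    pick_closest_reference,
    synthesize_domain,
    ungap,
)
from .numbering import ImgtPosition, scheme_constants
from .properties import classify, compare_residues, load_class_tables

__version__ = "0.1.0"

__all__ = [
    "GappedDomain",
    "ImgtPosition",
    "classify",
    "compare_residues",
    "compare_to_reference",
    "gap_sequence",
    "layout",
    "load_class_tables",
    "numbering",
    "parse_gapped",
    "pick_closest_reference",
    "profile",
    "properties",
    "render",
    "scheme_constants",
    "structure",
    "synthesize_domain",
    "trastuzumab_vh",
    "ungap",
]


def trastuzumab_vh() -> str:
    """The packaged trastuzumab VH amino-acid sequence (PDB 1n8z chain B)."""
    text = resources.files("collier.data").joinpath("trastuzumab_vh.fasta").read_text()
    return "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )
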