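"""FASTA and TSV input/output.

Plain FASTA holds ungapped sequences; gapped FASTA uses '.' for empty IMGT
positions (one 128-column record per domain; '-' is accepted on input and
normalised).  Difference tables are written as TSV with one row per
substitution or length difference.
"""

from __future__ import annotations

import sys
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import numbering
from .gapper import ComparisonResult, GappedDomain

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gapped_fasta",
    "read_gapped_fasta",
    "write_differences_tsv",
]


def read_fasta(path_or_handle) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file; gap characters are kept."""
    return [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], handle_or_path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, handle_or_path, "fasta")


def write_gapped_fasta(
    domains: Iterable[tuple[str, GappedDomain]], handle_or_path
) -> None:
    write_fasta(
        ((name, d.gapped_sequence()) for name, d in domains), handle_or_path
    )


def read_gapped_fasta(path_or_handle, strict: bool = False) -> list[tuple[str, GappedDomain]]:
    from .gapper import parse_gapped

    return [
        (name, parse_gapped(seq, strict=strict))
        for name, seq in read_fasta(path_or_handle)
    ]


DIFF_COLUMNS = (
    "position",
    "region",
    "query",
    "reference",
    "same_hydropathy",
    "same_volume",
    "same_physicochemical",
    "label",
)


def write_differences_tsv(result: ComparisonResult, handle: TextIO | None = None) -> None:
    """Write substitutions (and length differences, labelled as such) as TSV."""
    handle = handle or sys.stdout
    handle.write("\t".join(DIFF_COLUMNS) + "\n")
    rows = []
    for d in result.differences:
        ch = d.change
        rows.append(
            (
                d.position,
                numbering.region_of(d.position),
                d.query,
                d.reference,
                "" if ch is None else str(ch.same_hydropathy).lower(),
                "" if ch is None else str(ch.same_volume).lower(),
                "" if ch is None else str(ch.same_physicochemical).lower(),
                "unclassifiable" if ch is None else ch.label,
            )
        )
    for ld in result.length_differences:
        rows.append(
            (
                ld.position,
                numbering.region_of(ld.position),
                ld.query or ".",
                ld.reference or ".",
                "",
                "",
                "",
                "length difference",
            )
        )
    for row in sorted(rows, key=lambda r: r[0]):
        handle.write("\t".join(str(x) for x in row) + "\n")
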