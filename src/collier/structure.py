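"""V-domain extraction from 3D structures and backbone hydrogen bonds.

A chain (optionally restricted to an author-numbering range) is read from a
PDB file with gemmi; its amino-acid sequence can then be mapped onto IMGT
positions through the gapper, after which backbone hydrogen bonds can be
reported between IMGT positions for the two-layer overlay.

The bond criterion is geometric: a donor backbone nitrogen N(i) and an
acceptor carbonyl oxygen O(j) are bonded when their distance is at or
below a cutoff (default 3.5 Å) and the residues are at least two apart in
the chain.  No hydrogen atoms are required and the result is invariant
under rigid-body motion.  This is a deliberate simplification of
energy-based assignments (DSSP-style); bond sets from experimental
databases will differ in detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi

from .errors import CollierError
from .gapper import GappedDomain, gap_sequence
from .numbering import ImgtPosition

__all__ = [
    "StructResidue",
    "DomainStructure",
    "HBond",
    "read_structure",
    "map_to_imgt",
    "detect_hbonds",
    "backbone_hbond_indices",
    "write_synthetic_sheet_pdb",
]

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class StructResidue:
    code: str  # one-letter
    auth_num: int
    icode: str
    atoms: dict[str, tuple[float, float, float]]

    @property
    def missing_backbone(self) -> tuple[str, ...]:
        return tuple(a for a in BACKBONE if a not in self.atoms)


@dataclass
class DomainStructure:
    chain_id: str
    residues: list[StructResidue]
    domain: GappedDomain | None = None
    #: residue index (0-based, file order) -> ImgtPosition
    mapping: dict[int, ImgtPosition] = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)


@dataclass(frozen=True)
class HBond:
    donor: ImgtPosition
    acceptor: ImgtPosition
    distance: float


def read_structure(
    path, chain: str, auth_range: tuple[int, int] | None = None
) -> DomainStructure:
    """Read one chain of a PDB file into a DomainStructure (unmapped).

    ``auth_range`` restricts to an inclusive author residue-number interval.
    Residues with missing backbone atoms are retained and flagged.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    names = [ch.name for ch in model]
    if chain not in names:
        raise CollierError(
            f"chain {chain!r} not in structure; available chains: {', '.join(sorted(names))}"
        )
    residues: list[StructResidue] = []
    for res in model[chain]:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        if auth_range is not None and not (
            auth_range[0] <= res.seqid.num <= auth_range[1]
        ):
            continue
        atoms = {
            a.name: (a.pos.x, a.pos.y, a.pos.z)
            for a in res
            if a.name in BACKBONE
        }
        residues.append(
            StructResidue(
                code=gemmi.find_tabulated_residue(res.name).one_letter_code.upper(),
                auth_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
                atoms=atoms,
            )
        )
    return DomainStructure(chain_id=chain, residues=residues)


def map_to_imgt(ds: DomainStructure, strict: bool = False) -> DomainStructure:
    """Gap the extracted sequence and attach the residue→position map."""
    domain = gap_sequence(ds.sequence, strict=strict)
    ds.domain = domain
    ds.mapping = dict(enumerate(domain.occupied()))
    return ds


def _dist(p: tuple[float, float, float], q: tuple[float, float, float]) -> float:
    return math.dist(p, q)


def backbone_hbond_indices(
    ds: DomainStructure, cutoff: float = 3.5, min_separation: int = 2
) -> list[tuple[int, int, float]]:
    """(donor index, acceptor index, N···O distance) triples.

    Residues lacking an N cannot donate; residues lacking an O cannot
    accept.  Each directed pair is reported once.
    """
    out = []
    for i, ri in enumerate(ds.residues):
        n = ri.atoms.get("N")
        if n is None:
            continue
        for j, rj in enumerate(ds.residues):
            if abs(i - j) < min_separation:
                continue
            o = rj.atoms.get("O")
            if o is None:
                continue
            d = _dist(n, o)
            if d <= cutoff:
                out.append((i, j, d))
    return out


def detect_hbonds(
    ds: DomainStructure, cutoff: float = 3.5, min_separation: int = 2
) -> list[HBond]:
    """Backbone hydrogen bonds between mapped IMGT positions."""
    if ds.domain is None:
        map_to_imgt(ds)
    return [
        HBond(ds.mapping[i], ds.mapping[j], round(d, 3))
        for i, j, d in backbone_hbond_indices(ds, cutoff, min_separation)
        if i in ds.mapping and j in ds.mapping
    ]


def write_hbonds_tsv(bonds: list[HBond], handle) -> None:
    handle.write("donor\tacceptor\tdistance\n")
    for b in bonds:
        handle.write(f"{b.donor}\t{b.acceptor}\t{b.distance:.3f}\n")


def write_synthetic_sheet_pdb(
    path, sequence: str, chain: str = "A", row_length: int = 10
) -> None:
    """Write a synthetic PDB of the sequence folded into an ideal sheet.

    The backbone meanders in antiparallel rows of ``row_length`` residues:
    3.4 Å between neighbours along a row, 4.8 Å between rows, with each
    amide N displaced toward the previous row and each carbonyl O toward
    the next, so that aligned residues of adjacent rows form N···O contacts
    of 2.8 Å.  The geometry is idealised — it exists to exercise the
    hydrogen-bond detector deterministically, not to model a real fold.
    """
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    st = gemmi.Structure()
    st.name = "synthetic-sheet"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, aa in enumerate(sequence.upper()):
        row, col = divmod(i, row_length)
        x = (col if row % 2 == 0 else row_length - 1 - col) * 3.4
        y = row * 4.8
        res = gemmi.Residue()
        res.name = three.get(aa, "GLY")
        res.seqid = gemmi.SeqId(i + 1, " ")
        for name, element, (dx, dy, dz) in (
            ("N", "N", (0.0, -1.0, 0.0)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (0.8, 0.5, 0.3)),
            ("O", "O", (0.0, 1.0, 0.0)),
        ):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(x + dx, y + dy, dz)
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))
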