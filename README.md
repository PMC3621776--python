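# collier

Standardized numbering, amino-acid property classes and "Collier de
Perles" 2D bead plots for immunoglobulin (IG) and T-cell-receptor (TR)
variable domains.

Antibody engineers and immunoinformaticians compare V domains across
sequences and species by first *gapping* each sequence onto the IMGT
unique numbering: a fixed frame of 128 positions tiled into four framework
regions (FR1 1–26, FR2 39–55, FR3 66–104, FR4 118–128 — the nine
antiparallel beta strands) and three complementarity-determining regions
(CDR1 27–38, CDR2 56–65, CDR3 105–117 — the antigen-binding loops).  A CDR
shorter than its region capacity (12 / 10 / 13) leaves gaps at the top of
the loop; the loop lengths are summarized as `[a.b.c]`.  Every V domain is
pinned by five conserved positions — 1st-CYS 23, CONSERVED-TRP 41,
hydrophobic 89, 2nd-CYS 104, J-PHE/J-TRP 118 — and six framework anchors
(26, 39, 55, 66, 104, 118) that support the loops.

On top of the numbering, the package provides:

* **Property classes** — the 20 residues partitioned by hydropathy
  (3 classes), volume (5) and the 11 standard physicochemical classes,
  plus change characterisation (identical / very similar / … / dissimilar)
  between a query and a reference residue.
* **Statistical profiles** — per-position class frequencies over a set of
  gapped domains, with the "50 % or more hydrophobic" and "80 % dominant
  class" display statistics (thresholds inclusive).
* **Collier de Perles rendering** — deterministic SVG bead plots on one
  layer or two layers (the [A,B,E,D] / [G,F,C,C′,C″] beta sheets), with
  anchors as squares, conserved positions in red bold, CDR loops accented
  red/orange/purple, differences from a reference outlined in pink, and
  backbone hydrogen bonds from a 3D structure drawn as green lines
  (geometric N···O ≤ 3.5 Å criterion, sequence separation ≥ 2).
* **A fixture generator** — deterministic synthetic V-domain sequences
  with chosen CDR lengths, so every part of the package can be exercised
  without downloads.

## Worked example

Gap the trastuzumab VH domain (the V domain of PDB entry 1n8z, chain B;
the sequence ships with the package):

```
$ python -c "from importlib import resources; print(resources.files('collier.data')
  .joinpath('trastuzumab_vh.fasta').read_text())" > trastuzumab_vh.fasta
$ collier gap trastuzumab_vh.fasta --out trastuzumab_gapped.fasta
note: trastuzumab_VH: FR1 germline gap at position 10
note: trastuzumab_VH: FR3 germline gap at position 73
trastuzumab_VH	[8.8.13]
$ cat trastuzumab_gapped.fasta
>trastuzumab_VH
EVQLVESGG.GLVQPGGSLRLSCAASGFNI....KDTYIHWVRQAPGKGLEWVARIYPT.
.NGYTRYADSVK.GRFTISADTSKNTAYLQMNSLRAEDTAVYYCSRWGGDGFYAMDYWGQ
GTLVTVSS
```

The report line says the three CDR loops have lengths `[8.8.13]`: CDR1
`GFNIKDTY` leaves positions 31–34 empty, CDR2 `IYPTNGYT` leaves 60–61
empty, and the 13-residue CDR3 `SRWGGDGFYAMDY` fills its region exactly.
The two notes flag the standard human germline framework gaps (positions
10 and 73) that the gapper recognised.  Rendering is one more command:

```
$ collier draw trastuzumab_vh.fasta --mode physicochemical --out trastuzumab.svg
```

which writes a one-layer Collier de Perles with each bead coloured by its
physicochemical class.  `--layers 2 --pdb structure.pdb --chain B` adds
the two-layer view with the hydrogen-bond overlay; `collier profile`,
`collier compare`, `collier hbonds` and `collier synth` cover the rest of
the workflow (see `collier --help`).

The same operations are available as a library:

```python
from collier import gap_sequence, trastuzumab_vh

dom = gap_sequence(trastuzumab_vh())
dom.cdr_lengths        # (8, 8, 13)
dom.residue(104)       # 'C'  (2nd-CYS)
```

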