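# Methods

## Numbering model

V domains are laid onto the 128-position unique-numbering frame
(FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117,
FR4 118–128).  Loop gapping follows the "gaps at the top of the loop"
convention: for an observed CDR length *L* the occupied positions are the
first ⌈L/2⌉ and last ⌊L/2⌋ positions of the region.  This closed form is
the normative implementation; the equivalent middle-out removal order
(odd-capacity CDR3: 111, 112, 110, 113, …; even-capacity CDR1: 33, 32,
34, 31, …; CDR2: 61, 60, 62, 59, …) is kept as an independent oracle in
the test suite and checked exhaustively for every admissible length.  The
even-capacity tie-break (upper-middle removed first) is a documented
package convention; it reproduces the standard gap sets such as
{31,32,33,34} for an 8-residue CDR1.  CDR3 loops longer than 13 gain
insertion positions in the order 112.1, 111.1, 112.2, 111.2, … (display
order 111, 111.1, …, 112.1, 112), up to 20 insertions by default.

## Motif-based gapping

The gapper anchors an ungapped sequence on the conserved framework
residues: C at position 23, W at 41, C at 104 and F/W at 118, with FR2 and
FR4 at fixed widths (17 and 11).  Framework lengths are tried in a
deterministic preference order and the first assignment consistent with
all four anchors and the CDR capacities (CDR1 ≤ 12, CDR2 ≤ 10,
CDR3 ≤ 33) wins.

Frameworks are assumed at full capacity with one deliberate extension:
the two standard germline framework gaps of expressed human V domains —
position 10 in FR1 and position 73 in FR3 — are recognised.  Because the
2nd-CYS pins only the *sum* of the CDR2 length and the FR3 width, a
sequence with the position-73 gap also admits a full-FR3 parse with a
CDR2 one shorter; the two cannot be distinguished from motifs alone.  The
package resolves the ambiguity with a biological prior: full-capacity
frameworks are preferred, except that when FR1 needed the position-10 gap
(a germline-style sequence) the position-73 FR3 gap is preferred.  The two
gaps co-occur in essentially all expressed human V genes, so this yields
the conventional `[8.8.13]` delineation for trastuzumab-like sequences
while full-framework (e.g. synthetic) sequences parse exactly.  Any other
framework deletion must be supplied pre-gapped (128 '.'-gapped columns;
'-' accepted and normalised).  Germline-directory alignment — how the
reference web tool places framework gaps in general — is out of scope;
closest-reference selection over a *user-supplied* gapped directory uses
position-wise identity over co-occupied slots (ties to the earlier entry),
a documented stand-in for the undisclosed alignment scoring.

Conserved-slot mismatches (including a non-hydrophobic residue at 89) are
warnings by default so that engineered or unusual domains still render;
`strict=True` upgrades them to errors.

## Property classes

Class memberships live in one packaged text table
(`data/imgt_classes.tsv`), validated on load: 20 residues, and each of the
three dimensions (3 hydropathy, 5 volume, 11 physicochemical classes) a
partition.  The change-characterisation tiers default to: identical (same
residue), very similar (all three classes shared), similar (two), neutral
(one), dissimilar (none); the map is an argument, since different
humanization workflows weight changes differently.  Unknown residue codes
raise a distinct recoverable signal rather than a hard error.

## Profiles

Profiles count, per position, the occupying residues of a domain set and
their classes.  Frequencies are computed over the *classifiable residues
occupying* the position — gaps and unknown codes never dilute a
position's class frequencies, they only lower its occupancy.  (Whether the
reference web resource divides by occupancy or by the full set size is not
documented; occupied-only is this package's documented, configurable
choice.)  Both display thresholds are inclusive: a position is "50 %
hydrophobic" at exactly one half, and a class is dominant at exactly 0.8.
At any threshold above 0.5 at most one class can qualify.  The TSV
round-trip recovers counts from frequencies via the occupancy total, which
is exact when all occupying residues are classifiable.

## Structures and hydrogen bonds

PDB files are read with gemmi; one chain (optionally an author-number
range) is extracted with its backbone N/CA/C/O coordinates, and the
sequence is mapped to IMGT positions through the gapper.  Hydrogen bonds
use a purely geometric backbone criterion: donor N(i) to acceptor O(j)
distance ≤ 3.5 Å with |i − j| ≥ 2 in chain order.  The criterion needs no
hydrogens, is rigid-motion invariant and is fully testable on synthetic
coordinates; it is *not* the (undisclosed) assignment used by the
reference database, so bond sets will differ in detail from published
figures.  An energy-based (DSSP-style) criterion would be a drop-in
alternative.  Residues missing N cannot donate; missing O cannot accept;
such residues are retained and flagged.  The synthetic-sheet PDB writer
folds a sequence into idealised antiparallel rows (3.4 Å along a row,
4.8 Å between rows, amide N and carbonyl O displaced ±1 Å across rows) so
that aligned residues form 2.8 Å N···O contacts — a deterministic test
bed, not a physical model.

## Layout and rendering

The nine strands (A 1–15, B 16–26, C 39–46, C′ 47–55, C″ 66–74, D 75–84,
E 85–96, F 97–104, G 118–128 — a packaged table tiling the framework
regions, an approximation of the standard layout) are drawn as vertical
columns traversed serpentine-fashion with bottoms on a common baseline;
CDR loops are quadratic-Bézier arcs over the strands they connect, always
carrying the full region capacity of beads so that loop gaps appear as
empty beads at the loop top.  The two-layer view assigns strands to the
two beta sheets ([A,B,E,D] front, [G,F,C,C′,C″] back — configurable) and
offsets the back layer diagonally; each loop is drawn on its preceding
strand's layer.  Geometry constants (spacing 1.0 unit, bead radius 0.35,
arc rise 0.6 units per loop bead, layer offset 0.45) live in one config,
loadable from a `key = value` file.  Correctness is defined by invariants
— unique coordinates, full slot coverage, 9 strand / 3 loop blocks, and a
bounded step (≤ 3 spacings) between consecutive positions *on the same
layer* (layer crossings are exempt, as the layers are offset) — not by
pixel fidelity to the reference website.

SVG output is byte-deterministic: fixed element order (bonds under beads,
back layer under front), fixed attribute order, two-decimal coordinates,
no metadata.  Only the field conventions are contractual: anchors as
squares, conserved letters red and bold, hydrophobic beads blue in
hydropathy mode, CDR1/2/3 accents red/orange/purple, difference borders
pink, hydrogen bonds green.  All other colours are a documented default
palette.

## Synthetic data

`synthesize_domain(cdr_lengths, seed)` emulates a numberable V domain:
full-capacity frameworks, the conserved C/W/C and F-or-W at positions
23/41/104/118, a hydrophobic residue at 89, and all other residues drawn
uniformly from the 18 standard codes *excluding C and W*, so the
conserved motifs are provably unambiguous and gapping round-trips exactly
(length 93 + a + b + c).  What the generator does not emulate: germline
framework gaps (exercised instead by the packaged trastuzumab VH and by
pre-gapped fixtures), realistic residue composition and covariation, and
allelic structure.  Passing tests therefore demonstrate the numbering,
profiling and rendering machinery, not recognition performance on
arbitrary natural sequences — natural human V domains are covered exactly
insofar as their framework gaps are the standard 10/73 pattern.

## Problem sizes

The test suite and the acceptance script run on synthetic domains of
~93–135 residues; exhaustive loop-gap checks cover all 38 admissible
lengths; round-trip checks use ~1200 generated sequences over a grid of
CDR-length triples; hydrogen-bond checks use a 122-residue synthetic
sheet (100 bonds).  All sizes were chosen as the smallest that exercise
every code path exhaustively; everything completes in seconds.

## Known limitations

* V domains only — constant (C) and groove (G) domain numbering and
  layouts are out of scope.
* Framework gaps other than positions 10 and 73 require pre-gapped input;
  CDR3 insertions are not representable in pre-gapped 128-column input.
* Closest-reference selection is identity-based, not an alignment model,
  and germline gene/allele naming is out of scope.
* The hydrogen-bond criterion is geometric backbone N···O only; sidechain
  bonds and contact-type catalogues are not computed.
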