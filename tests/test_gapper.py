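"""Motif-based gapping, round-trips, reference comparison, fixtures."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collier import gap_sequence, synthesize_domain, ungap
from collier.errors import NotNumberableError
from collier.gapper import (
    _FIXTURE_ALPHABET,
    compare_to_reference,
    detect_anchors,
    parse_gapped,
    pick_closest_reference,
)
from collier.numbering import ImgtPosition

triples = st.tuples(
    st.integers(0, 12), st.integers(0, 10), st.integers(0, 13)
)


def test_detect_anchors_on_generator_output():
    seq = synthesize_domain((8, 8, 13), seed=1)
    hits = detect_anchors(seq)
    assert (hits.cys23, hits.trp41, hits.cys104, hits.j118) == (22, 36, 97, 111)
    assert hits.cdr_lengths == (8, 8, 13)
    assert hits.fr1_length == 26 and hits.fr3_length == 39


def test_no_cysteine_fails_naming_first_cys():
    with pytest.raises(NotNumberableError) as exc:
        detect_anchors("A" * 100)
    assert exc.value.anchor == "1st-CYS"


def test_cdr1_above_capacity_is_not_numberable():
    # hand-built sequence with a 15-residue CDR1; other residues avoid C/W
    fr1 = "A" * 22 + "C" + "AAA"
    fr2 = "AA" + "W" + "A" * 14
    fr3 = "A" * 23 + "L" + "A" * 14 + "C"
    seq = fr1 + "G" * 15 + fr2 + "G" * 8 + fr3 + "G" * 13 + "W" + "A" * 10
    with pytest.raises(NotNumberableError):
        detect_anchors(seq)


def test_gap_sequence_8_8_13():
    dom = gap_sequence(synthesize_domain((8, 8, 13), seed=1))
    assert len(dom.slots) == 128
    assert dom.cdr_lengths == (8, 8, 13)
    assert {p.number for p in dom.gaps()} == {31, 32, 33, 34, 60, 61}
    assert dom.warnings == []


def test_gap_sequence_full_capacity_has_no_gaps():
    dom = gap_sequence(synthesize_domain((12, 10, 13), seed=2))
    assert dom.gaps() == []
    assert len(dom.occupied()) == 128


def test_trastuzumab_vh_cdr_lengths(trastuzumab):
    dom = gap_sequence(trastuzumab)
    assert dom.cdr_lengths == (8, 8, 13)
    assert {p.number for p in dom.gaps()} == {10, 31, 32, 33, 34, 60, 61, 73}
    assert dom.residue(23) == "C" and dom.residue(41) == "W"
    assert dom.residue(104) == "C" and dom.residue(118) == "W"
    assert ungap(dom) == trastuzumab


def test_long_cdr3_uses_insertion_positions():
    seq = synthesize_domain((8, 8, 17), seed=3)
    dom = gap_sequence(seq)
    assert dom.cdr_lengths == (8, 8, 17)
    inserted = [str(p) for p in dom.occupied() if p.insertion]
    assert inserted == ["111.1", "111.2", "112.2", "112.1"]  # display order
    assert ungap(dom) == seq


@settings(max_examples=80, deadline=None)
@given(triples, st.integers(0, 2**20))
def test_roundtrip_ungap_gap_identity(cdr_lengths, seed):
    seq = synthesize_domain(cdr_lengths, seed)
    dom = gap_sequence(seq)
    assert ungap(dom) == seq
    assert dom.cdr_lengths == cdr_lengths
    assert len(dom.occupied()) + len(dom.gaps()) == 128


def test_all_gap_cdrs_leaves_framework_only():
    seq = synthesize_domain((0, 0, 0), seed=4)
    assert len(seq) == 93
    dom = gap_sequence(seq)
    assert ungap(dom) == seq
    assert len(dom.gaps()) == 35


def test_pregapped_roundtrip(domain_8813):
    text = domain_8813.gapped_sequence()
    assert len(text) == 128
    reparsed = parse_gapped(text)
    assert reparsed.slots == domain_8813.slots
    assert "." not in reparsed.ungapped()


def test_pregapped_accepts_dash_and_rejects_wrong_width():
    with pytest.raises(ValueError):
        parse_gapped("ACDE")
    dom = parse_gapped("-" * 22 + "C" + "-" * 105)
    assert dom.residue(23) == "C"


def test_conserved_mismatch_is_warning_not_error():
    seq = list(synthesize_domain((8, 8, 13), seed=5))
    seq[26 + 8 + 17 + 8 + 23] = "D"  # position 89, hydrophilic
    dom = gap_sequence("".join(seq))
    assert any("89" in w for w in dom.warnings)
    with pytest.raises(NotNumberableError):
        gap_sequence("".join(seq), strict=True)


def test_compare_identical_is_empty(domain_8813):
    result = compare_to_reference(domain_8813, domain_8813)
    assert result.differences == [] and result.length_differences == []


def test_compare_single_substitution(full_domain, edit_domain):
    current = full_domain.residue(50)
    other = next(r for r in _FIXTURE_ALPHABET if r != current)
    mutated = edit_domain(full_domain, p50=other)
    result = compare_to_reference(mutated, full_domain)
    assert [d.position for d in result.differences] == [ImgtPosition(50)]
    assert result.length_differences == []
    d = result.differences[0]
    assert (d.query, d.reference) == (other, current)
    assert d.change is not None and d.change.label != "identical"


def test_compare_cdr3_length_difference(domain_8813, edit_domain):
    shorter = edit_domain(domain_8813, p111=None)  # CDR3 12 vs 13
    result = compare_to_reference(shorter, domain_8813)
    assert result.differences == []
    assert [ld.position for ld in result.length_differences] == [ImgtPosition(111)]
    ld = result.length_differences[0]
    assert ld.query is None and ld.reference is not None


def test_compare_counts_symmetric(full_domain, edit_domain, domain_8813):
    mutated = edit_domain(full_domain, p5="H", p70=None)
    fwd = compare_to_reference(mutated, full_domain)
    rev = compare_to_reference(full_domain, mutated)
    assert len(fwd.differences) == len(rev.differences)
    assert len(fwd.length_differences) == len(rev.length_differences)


def test_pick_closest_reference(full_domain, edit_domain):
    near = edit_domain(full_domain, p5="H")
    far = edit_domain(full_domain, p5="H", p6="H", p7="H")
    name, ref, ident = pick_closest_reference(full_domain, [("far", far), ("near", near)])
    assert name == "near" and ident == 127 / 128
    # with the query itself present, identity 1.0 wins
    assert pick_closest_reference(full_domain, [("self", full_domain)])[2] == 1.0
    # tie: first in directory order
    assert pick_closest_reference(full_domain, [("a", near), ("b", near)])[0] == "a"
    with pytest.raises(ValueError):
        pick_closest_reference(full_domain, [])


def test_synthesize_deterministic_and_capacity_checked():
    assert synthesize_domain((8, 8, 13), 1) == synthesize_domain((8, 8, 13), 1)
    assert synthesize_domain((8, 8, 13), 1) != synthesize_domain((8, 8, 13), 2)
    assert len(synthesize_domain((3, 4, 5), 0)) == 93 + 12
    with pytest.raises(ValueError):
        synthesize_domain((13, 8, 13), 0)
    with pytest.raises(ValueError):
        synthesize_domain((8, -1, 13), 0)
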