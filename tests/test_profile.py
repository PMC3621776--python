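"""Statistical profiles: frequencies, occupancy, threshold statistics."""

import io

import pytest

from collier import gap_sequence, synthesize_domain
from collier.numbering import ImgtPosition
from collier.profile import (
    build_profile,
    dominant_class,
    hydrophobic_positions,
    read_profile_tsv,
    write_profile_tsv,
)

P50 = ImgtPosition(50)


def variants(full_domain, edit_domain, residues_at_50):
    return [edit_domain(full_domain, p50=r) for r in residues_at_50]


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        build_profile([])


def test_single_domain_has_unanimous_frequencies(domain_8813):
    prof = build_profile([domain_8813])
    assert prof.source_count == 1
    for pos in domain_8813.occupied():
        freqs = [
            prof.frequency(pos, "physicochemical", c)
            for c in prof.table.physicochemical_classes
        ]
        assert max(freqs) == 1.0 and sum(freqs) == pytest.approx(1.0)


def test_half_hydrophobic_position(full_domain, edit_domain):
    prof = build_profile(variants(full_domain, edit_domain, "IR"))
    assert prof.frequency(P50, "hydropathy", "hydrophobic") == pytest.approx(0.5)
    assert prof.frequency(P50, "hydropathy", "hydrophilic") == pytest.approx(0.5)


def test_occupancy_counts_gapped_domains():
    doms = [gap_sequence(synthesize_domain((12, 10, 13), s)) for s in range(3)]
    doms.append(gap_sequence(synthesize_domain((12, 8, 13), 3)))  # gapped at 60/61
    prof = build_profile(doms)
    assert prof.occupancy[ImgtPosition(60)] == 3
    assert prof.occupancy[ImgtPosition(50)] == 4
    assert prof.source_count == 4


def test_hydrophobic_threshold_is_inclusive(full_domain, edit_domain):
    two_of_four = build_profile(variants(full_domain, edit_domain, "ILRR"))
    assert P50 in hydrophobic_positions(two_of_four, threshold=0.5)
    one_of_four = build_profile(variants(full_domain, edit_domain, "IRRR"))
    assert P50 not in hydrophobic_positions(one_of_four, threshold=0.5)
    assert P50 not in hydrophobic_positions(two_of_four, threshold=1.0)


def test_hydrophobic_positions_antitone_in_threshold(full_domain, edit_domain):
    prof = build_profile(variants(full_domain, edit_domain, "ILVRGD"))
    previous = None
    for thr in (0.1, 0.3, 0.5, 0.8, 1.0):
        current = hydrophobic_positions(prof, thr)
        if previous is not None:
            assert current <= previous
        previous = current


def test_dominant_class_inclusive_80_boundary(full_domain, edit_domain):
    # 4 of 5 aliphatic: frequency exactly 0.8
    prof = build_profile(variants(full_domain, edit_domain, "IVLAR"))
    assert dominant_class(prof, 50, "physicochemical", 0.8) == "aliphatic"
    # 3 of 4 = 0.75 misses the 0.8 bar
    prof2 = build_profile(variants(full_domain, edit_domain, "IVLR"))
    assert dominant_class(prof2, 50, "physicochemical", 0.8) is None


def test_dominant_class_unanimous_and_unique(full_domain, edit_domain):
    prof = build_profile(variants(full_domain, edit_domain, "KKKK"))
    assert dominant_class(prof, 50, "physicochemical") == "basic"
    # above 0.5 at most one class can qualify at any position/dimension
    mixed = build_profile(variants(full_domain, edit_domain, "IKGD"))
    for dim in ("hydropathy", "volume", "physicochemical"):
        for pos in mixed.positions():
            qualifying = [
                c
                for c in mixed.table.catalog(dim)
                if mixed.frequency(pos, dim, c) >= 0.51
            ]
            assert len(qualifying) <= 1


def test_dominant_class_rejects_unknown_dimension(domain_8813):
    prof = build_profile([domain_8813])
    with pytest.raises(ValueError):
        dominant_class(prof, 50, "charge")


def test_unclassifiable_residue_in_occupancy_not_frequencies(full_domain, edit_domain):
    prof = build_profile(variants(full_domain, edit_domain, "XII"))
    assert prof.occupancy[P50] == 3
    assert prof.classifiable(P50) == 2
    assert prof.frequency(P50, "hydropathy", "hydrophobic") == pytest.approx(1.0)


def test_frequencies_sum_to_one_over_classifiable(domain_8813, full_domain):
    prof = build_profile([domain_8813, full_domain])
    for pos in prof.positions():
        for dim in ("hydropathy", "volume", "physicochemical"):
            total = sum(
                prof.frequency(pos, dim, c) for c in prof.table.catalog(dim)
            )
            if prof.classifiable(pos, dim):
                assert total == pytest.approx(1.0, abs=1e-9)


def test_profile_tsv_roundtrip(full_domain, edit_domain):
    prof = build_profile(variants(full_domain, edit_domain, "ILRG"))
    buf = io.StringIO()
    write_profile_tsv(prof, buf)
    buf.seek(0)
    loaded = read_profile_tsv(buf)
    assert loaded.source_count == prof.source_count
    assert loaded.occupancy == prof.occupancy
    assert hydrophobic_positions(loaded) == hydrophobic_positions(prof)
    assert loaded.frequency(P50, "hydropathy", "hydrophobic") == pytest.approx(
        prof.frequency(P50, "hydropathy", "hydrophobic"), abs=1e-6
    )
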