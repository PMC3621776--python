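import pytest

from collier import gap_sequence, synthesize_domain, trastuzumab_vh
from collier.gapper import GappedDomain, parse_gapped
from collier.properties import load_class_tables


@pytest.fixture(scope="session")
def table():
    return load_class_tables()


@pytest.fixture(scope="session")
def trastuzumab() -> str:
    return trastuzumab_vh()


@pytest.fixture(scope="session")
def domain_8813() -> GappedDomain:
    return gap_sequence(synthesize_domain((8, 8, 13), seed=1))


@pytest.fixture(scope="session")
def full_domain() -> GappedDomain:
    """A domain at full CDR capacities: 128 occupied slots, no gaps."""
    return gap_sequence(synthesize_domain((12, 10, 13), seed=7))


@pytest.fixture
def edit_domain():
    """Edit residues/gaps of a domain via its gapped string, re-parsing."""

    def _edit(domain: GappedDomain, **changes: str | None) -> GappedDomain:
        chars = list(domain.gapped_sequence())
        positions = sorted(domain.slots)
        index = {p.number: i for i, p in enumerate(positions) if p.insertion == 0}
        for key, value in changes.items():
            chars[index[int(key.lstrip("p"))]] = "." if value is None else value
        return parse_gapped("".join(chars))

    return _edit
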