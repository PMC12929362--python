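import pytest

from aptadna import build_gc_pair, build_helix, convert_structure
from aptadna.sequences import A6_RNA


@pytest.fixture(scope="session")
def single_u():
    """One uridine nucleotide, heavy atoms only."""
    return build_helix("U")


@pytest.fixture(scope="session")
def single_u_h():
    """One uridine nucleotide including hydrogens."""
    return build_helix("U", include_hydrogens=True)


@pytest.fixture(scope="session")
def a6_helix():
    """Idealized A-form helix for the 60-nt A6 aptamer RNA sequence."""
    return build_helix(A6_RNA)


@pytest.fixture(scope="session")
def a6_converted(a6_helix):
    return convert_structure(a6_helix)


@pytest.fixture(scope="session")
def gc_pair():
    return build_gc_pair()
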