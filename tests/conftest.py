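import pytest

from graftkit import kabat_number_sequence
from graftkit.kabat import RegionPartition
from graftkit.refdata import V_REGION_LIBRARY
from graftkit.synth import make_toy_complex


@pytest.fixture(scope="session")
def numbered_library():
    """Every built-in V-region pair, Kabat numbered."""
    return {
        name: (kabat_number_sequence(vh, "H", name),
               kabat_number_sequence(vl, "L", name))
        for name, (vh, vl) in V_REGION_LIBRARY.items()
    }


@pytest.fixture(scope="session")
def donor(numbered_library):
    return numbered_library["M3/38"]


@pytest.fixture(scope="session")
def acceptor_4nry(numbered_library):
    return numbered_library["4NRY"]


@pytest.fixture(scope="session")
def partition():
    return RegionPartition.default()


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=0)
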