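import numpy as np
import pytest

from edascan import MockEngine, RHFEngine
from edascan.molecules import acetone, cyanide, cyanide_acetone_pair
from edascan.optimize import relax


@pytest.fixture(scope="session")
def rhf_engine():
    return RHFEngine()


@pytest.fixture(scope="session")
def mock_engine():
    return MockEngine()


@pytest.fixture(scope="session")
def relaxed_fragments(rhf_engine):
    """Acetone and cyanide relaxed once per session at RHF/STO-3G."""
    ac = relax(acetone(), rhf_engine).geometry
    cn = relax(cyanide(), rhf_engine).geometry
    return ac, cn


@pytest.fixture(scope="session")
def cn_acetone_pair(relaxed_fragments):
    ac, cn = relaxed_fragments
    return cyanide_acetone_pair(ac, cn)


@pytest.fixture(scope="session")
def mock_pair():
    """Template-geometry pair for mock-engine pipeline tests."""
    return cyanide_acetone_pair()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231004)
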