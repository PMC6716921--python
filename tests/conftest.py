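import numpy as np
import pytest

from ampminer import data as fixtures
from ampminer import synthetic_data as sd


@pytest.fixture(scope="session")
def beta_records():
    return fixtures.load_beta_defensins()


@pytest.fixture(scope="session")
def ovod_records():
    return fixtures.load_ovodefensins()


@pytest.fixture(scope="session")
def precursor_records():
    return fixtures.load_cathelicidin_precursors()


@pytest.fixture(scope="session")
def certified_genome():
    """Reference synthetic genome (all published AMPs + 50 decoys)."""
    return sd.certified_genome(seed=0)


@pytest.fixture(scope="session")
def emulated_block():
    """Scaled-down emulation of the published syntenic block."""
    return sd.emulated_cluster_scaffold(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
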