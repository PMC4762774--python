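import numpy as np
import pytest

import xpindex as xp


@pytest.fixture(scope="session")
def xanthone():
    return xp.build_xanthone()


@pytest.fixture(scope="session")
def table1():
    return xp.load_table1()


@pytest.fixture(scope="session")
def dbxth_28():
    """The 2,8-dibrominated congener with idealized coordinates."""
    return xp.idealized_geometry(xp.SubstitutionPattern((2, 8)))


@pytest.fixture
def rng():
    return np.random.default_rng(20160222)
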