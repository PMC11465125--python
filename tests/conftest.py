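import numpy as np
import pytest

import irisphylo as ip


@pytest.fixture(scope="session")
def color_table():
    return ip.make_color_table()


@pytest.fixture(scope="session")
def balanced4():
    """Symmetric 4-tip tree with unit branches."""
    return ip.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
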