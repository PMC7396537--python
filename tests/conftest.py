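import warnings

import numpy as np
import pytest

from budburst.synthetic import default_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced synthetic study reused across tests (6 trees per group)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return default_scenario(11, trees_per_group=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
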