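import numpy as np
import pytest

from pippet.domain import FilterConfig
from pippet.fixtures import cultural_table_pair, experiment1_banks
from pippet.priors import build_bank


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free configuration: deterministic filter runs."""
    return FilterConfig.from_defaults(event_noise_scale=0.0,
                                      phase_noise_scale=0.0)


@pytest.fixture(scope="session")
def banks():
    """(european, malian) two-interval template banks."""
    return experiment1_banks()


@pytest.fixture(scope="session")
def table_pair():
    """(hierarchical, flattened) synthetic metrical tables."""
    return cultural_table_pair(seed=0)


@pytest.fixture(scope="session")
def hier_bank(table_pair):
    return build_bank(table_pair[0])


@pytest.fixture(scope="session")
def flat_bank(table_pair):
    return build_bank(table_pair[1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
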