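import numpy as np
import pytest

from ednaq.cli import make_toy_fixture
from ednaq.simulator import default_config, simulate_survey


@pytest.fixture(scope="session")
def toy():
    """Tiny survey with censored, contaminated and inhibited replicates."""
    return make_toy_fixture(seed=0)


@pytest.fixture(scope="session")
def small_survey():
    """A seeded 10x20 survey at the reference parameters, M=K=2."""
    return simulate_survey(default_config(M=2, K=2, p_c=0.05, p_h=0.1,
                                          seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
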