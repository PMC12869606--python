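import numpy as np
import pytest

from promarch import simulate


@pytest.fixture(scope="session")
def small_study():
    """A 60-promoter synthetic study shared across read-only tests."""
    genome, truth = simulate.make_genome(n_promoters=60, seed=11)
    return genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
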