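import numpy as np
import pytest

from glaucokit.synthetic_data import (
    OrthogroupConfig,
    gen_orthogroups,
)


@pytest.fixture(scope="session")
def og_fixture():
    """One seeded orthogroup table with planted filter truth."""
    return gen_orthogroups(OrthogroupConfig(seed=11, n_ogs=100, pass_fraction=0.4))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
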