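import numpy as np
import pytest

from petnets import generate_cohort, make_fixture


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-default synthetic cohort, shared across tests."""
    return generate_cohort(make_fixture("paper-default", seed=0))


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(make_fixture("strong-effect", seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
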