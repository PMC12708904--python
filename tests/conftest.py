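import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rumordyn as rd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 400-record corpus shared across read-only tests."""
    return rd.generate_corpus(rd.GeneratorConfig(n_records=400, seed=11))


@pytest.fixture(scope="session")
def medium_corpus():
    """An 8,000-record corpus for recovery checks that need statistics."""
    return rd.generate_corpus(rd.GeneratorConfig(n_records=8000, seed=23))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
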