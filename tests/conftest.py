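import numpy as np
import pytest
from hypothesis import settings

from thinpred import INARParams, generate_inar

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inar_series():
    """A long INAR(1) path with alpha=0.6, lam=4: mean 10, lag-1 acf 0.6."""
    return generate_inar(INARParams(alpha=0.6, lam=4.0, length=30_000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
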