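import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    """A fixed 25-tip ultrametric pure-birth tree at the study depth."""
    from opermorph import generate_tree

    return generate_tree(25, 23.0, seed=42)
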