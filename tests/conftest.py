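import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_ref(rng):
    """Factory for random DNA reference strings."""

    def make(n: int = 258) -> str:
        return "".join("ACGT"[i] for i in rng.integers(4, size=n))

    return make
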