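import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_instance(rng):
    """A standardized 50x10 regression instance with a 3-sparse signal."""
    X = rng.standard_normal((50, 10))
    beta = np.zeros(10)
    beta[:3] = [2.0, -1.0, 0.5]
    y = X @ beta + rng.standard_normal(50)
    X = (X - X.mean(0)) / X.std(0)
    y = y - y.mean()
    return X, y, beta
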