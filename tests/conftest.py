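import numpy as np
import pytest

from fingerpls import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default 49x80 synthetic dataset, shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_xy(seed: int, n: int = 20, p: int = 10):
    """Small random regression problem for oracle comparisons."""
    r = np.random.default_rng(seed)
    X = r.standard_normal((n, p))
    beta = r.standard_normal(p)
    y = X @ beta + 0.1 * r.standard_normal(n)
    return X, y
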