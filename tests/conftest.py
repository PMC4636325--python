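import numpy as np
import pytest

from penregsim import generate_dataset, scenario


def random_pd_correlation(k, rng):
    """Random positive-definite correlation matrix via a random Gram matrix."""
    A = rng.standard_normal((k + 3, k))
    S = A.T @ A / (k + 3) + 0.1 * np.eye(k)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


@pytest.fixture(scope="session")
def scenario_b():
    return scenario("B", n=50)


@pytest.fixture(scope="session")
def dataset_b50(scenario_b):
    return generate_dataset(scenario_b, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
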