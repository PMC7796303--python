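import numpy as np
import pytest

from sfqsar import SyntheticSpec, generate_classification_fixture, generate_regression_fixture


@pytest.fixture(scope="session")
def linear_task():
    """n=200, 5 informative descriptors, sigma=0.3 — the MLP recovery task."""
    spec = SyntheticSpec(n=200, n_descriptors=5, n_informative=5,
                         noise_sd=0.3, seed=2000)
    return generate_regression_fixture(spec)


@pytest.fixture(scope="session")
def separable_task():
    """Two well-separated Gaussian classes (Bayes accuracy ≈ 1)."""
    spec = SyntheticSpec(n=200, n_descriptors=10, n_informative=3,
                         class_separation=6, seed=42)
    return generate_classification_fixture(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
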