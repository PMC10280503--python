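import pytest

from agebrf.pipeline import train_default_pipeline
from agebrf.synthetic import generate_samples


@pytest.fixture(scope="session")
def train_samples():
    """100-image training split (50 benign / 50 malignant) at defaults."""
    return generate_samples(50, 50, seed=2024)


@pytest.fixture(scope="session")
def test_samples():
    """40-image held-out split (20/20) at defaults."""
    return generate_samples(20, 20, seed=2025)


@pytest.fixture(scope="session")
def default_models(train_samples):
    """Segmenter + classifier trained at the documented default hyperparameters."""
    return train_default_pipeline(train_samples, seed=7)


@pytest.fixture(scope="session")
def small_samples():
    """A cheap 12-image dataset for unit tests."""
    return generate_samples(6, 6, seed=5)
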