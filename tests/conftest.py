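import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radhub.simulate import SyntheticConfig, generate_collection

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_collection():
    """The full five-dataset study at its default design, seed 1."""
    config = SyntheticConfig(seed=1)
    datasets, truth, catalog = generate_collection(config)
    return config, datasets, truth, catalog


@pytest.fixture(scope="session")
def small_collection():
    """A reduced three-dataset study for fast pipeline/io tests."""
    config = SyntheticConfig(
        n_genes=300,
        n_modules=3,
        module_sizes=(60, 60, 60),
        n_datasets=3,
        samples_per_dataset=(40, 36, 32),
        conditions_per_dataset=(4, 3, 3),
        seed=5,
    )
    datasets, truth, catalog = generate_collection(config)
    return config, datasets, truth, catalog


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
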