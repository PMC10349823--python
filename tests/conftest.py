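import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermomorph import SimulationConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """15 families with unequal sampling; used by several modules."""
    rng = np.random.default_rng(11)
    sizes = [int(x) for x in rng.integers(12, 40, size=15)]
    return generate_dataset(
        SimulationConfig(n_families=15, species_per_family=sizes, seed=4)
    )


@pytest.fixture(scope="session")
def small_vcv(small_dataset):
    return small_dataset.family_vcv()
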