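import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_config():
    """A fast-but-structured generator configuration for unit tests."""
    from emp_mirnet.synthdata import SyntheticConfig

    return SyntheticConfig(
        n_features=80,
        n_samples=30,
        n_network=25,
        n_emp_associated=35,
        n_expressed=50,
        edge_density=0.04,
        hub_degree=6,
        n_regions=6,
        enriched_region_size=12,
        enriched_overlap=7,
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    from emp_mirnet.synthdata import sample_dataset

    return sample_dataset(small_config)
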