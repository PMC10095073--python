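import numpy as np
import pytest
from hypothesis import HealthCheck, settings

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
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small cohort for fast unit tests (not the acceptance-scale demo)."""
    from driverprog.synthetic_data import demo_spec

    return demo_spec(
        n_genes=60,
        n_edges=240,
        n_tumor_good=12,
        n_tumor_bad=12,
        n_normal=8,
        n_planted_genes=6,
    )


@pytest.fixture(scope="session")
def tiny_network(tiny_spec):
    from driverprog.synthetic_data import generate_network

    return generate_network(tiny_spec)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tiny_network):
    from driverprog.synthetic_data import generate_cohort

    return generate_cohort(tiny_spec, tiny_network)
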