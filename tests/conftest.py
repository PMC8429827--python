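import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scnet import SyntheticSpec, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def amygdala_cohort():
    """Null two-group cohort over the amygdala atlas (29 + 40 subjects)."""
    return generate_cohort(SyntheticSpec(structures=("amygdala",)), seed=101)


@pytest.fixture(scope="session")
def full_cohort():
    """Null two-group cohort over all three structures."""
    return generate_cohort(SyntheticSpec(), seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_connectivity(rng, n, density=0.6):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    return w + w.T
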