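import numpy as np
import pytest

from rsband.simulate import CohortSimSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny effect-free cohort shared by pipeline-level tests."""
    spec = CohortSimSpec("demo", 3, 3, grid_shape=(16, 16, 16), seed=42)
    return simulate_cohort(spec)
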