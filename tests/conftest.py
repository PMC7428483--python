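import numpy as np
import pytest

from learnconn import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny but complete cohort for pipeline-level tests."""
    config = synthetic.SimulationConfig(
        n_subjects=6, volumes=60, seed=7
    ).scaled(0.15)
    return synthetic.simulate_cohort(config)


@pytest.fixture(scope="session")
def learning_cohort():
    """Reduced-scale cohort restricted to the learning family."""
    config = synthetic.SimulationConfig(
        n_subjects=12, volumes=80, seed=11,
        conditions=("rest", "EL-learn", "TE-learn"),
    ).scaled(0.25)
    return synthetic.simulate_cohort(config)
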