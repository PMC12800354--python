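import numpy as np
import pytest

from histotx import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-patient cohort with strong texture signal, reused across tests."""
    return generate_cohort(CohortConfig(n_patients=10, texture_effect=2.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
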