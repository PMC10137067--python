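import numpy as np
import pytest

from hccfusion import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One standard planted two-subtype cohort, shared across read-only tests."""
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
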