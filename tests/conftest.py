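import numpy as np
import pytest

from radiolik import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A 100 + 100 synthetic cohort with strongly separated planted features."""
    return generate_cohort(
        SyntheticConfig(n_malignant=100, n_benign=100, seed=7, effect_size=3.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
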