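import numpy as np
import pytest

from scovnet import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects x 12 regions, null effect — the bundled smoke fixture."""
    return generate_cohort(
        SyntheticConfig(n_subjects=20, n_regions=12, n_modules=3, seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
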