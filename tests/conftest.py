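import numpy as np
import pytest

from bodyrad.phantom import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 phantom patients with images, shared across read-only tests."""
    cfg = CohortConfig(n_patients=20, seed=3, image_shape=(96, 96))
    patients, slices = generate_cohort(cfg)
    return cfg, patients, slices


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
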