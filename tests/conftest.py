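import numpy as np
import pandas as pd
import pytest

from pnetrad import synthetic


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return synthetic.generate_cohort(synthetic.default_profile(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_roi():
    """A 4x4x4 random-intensity ROI with an irregular mask for oracle tests."""
    gen = np.random.default_rng(7)
    vol = gen.integers(0, 120, size=(4, 4, 4)).astype(float)
    mask = gen.random((4, 4, 4)) > 0.25
    mask[0, 0, 0] = True  # guarantee nonempty
    return vol, mask
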