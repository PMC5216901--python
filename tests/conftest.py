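import numpy as np
import pytest

from psitrap import synthetic


@pytest.fixture(scope="session")
def alpha_truth():
    return synthetic.KineticGroundTruth.alpha_dm()


@pytest.fixture(scope="session")
def alpha_images(alpha_truth):
    """One noisy streak image per time range, seed 1."""
    return synthetic.gen_streak_set(alpha_truth, seed=1)


@pytest.fixture(scope="session")
def absorption_77k():
    grid = np.arange(600.0, 750.0 + 0.25, 0.5)
    return synthetic.gen_absorption(synthetic.QY_BANDS_77K, grid)
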