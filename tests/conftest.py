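import numpy as np
import pytest
from hypothesis import settings

from imprint15 import melt

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def calibration():
    """Noise-free spiked-standard calibration shared across melt tests."""
    return melt.fit_calibration(melt.make_standards())


@pytest.fixture()
def rng():
    return np.random.default_rng(20220104)
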