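import logging

import numpy as np
import pytest

from dendroscan import SimConfig

logging.getLogger("dendroscan").setLevel(logging.ERROR)


@pytest.fixture
def small_cfg():
    """A short, small-image configuration for fast image-path tests."""
    return SimConfig(duration_s=3.0, stim_onset_s=1.6, n_pixels=128,
                     motion_max_px=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
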