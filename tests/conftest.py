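import warnings

import numpy as np
import pytest

from armbr.synthesis import make_scene

# segment-rejection warnings during pipeline runs are expected noise in tests
warnings.filterwarnings("ignore", message="rejected .* high-voltage")


@pytest.fixture(scope="session")
def standard_scene():
    """The canonical synthetic scene: 32 ch, 128 Hz, 60 s, 20 blinks/min,
    100 uV blink peak over 10 uV-rms background."""
    return make_scene(32, 128.0, 60.0, 20.0, peak_uV=100.0, background_rms_uV=10.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
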