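import numpy as np
import pytest

from leafsense.synthesize import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Reduced-resolution generator config for fast unit tests."""
    return SynthConfig(n_images=4, image_width=240, image_height=320,
                       texture_effect=80.0, seed=5)
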