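import numpy as np
import pytest

from shootcount.synthetic_data import SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 64x64 desk-scale scene with a handful of shoots."""
    return SceneSpec(image_height=64, image_width=64, count_range=(8, 20),
                     blob_sigma_range=(1.0, 2.0), background_class="grass")
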