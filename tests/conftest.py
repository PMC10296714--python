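import numpy as np
import pytest

from endofeat import SynthImageSpec, make_images


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lesion_batch():
    """Small synthetic image batch shared across tests (48x48, 4 per class)."""
    spec = SynthImageSpec(size=(48, 48), n_per_class=4, seed=7)
    images, labels, masks = make_images(spec)
    return spec, images, labels, masks
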