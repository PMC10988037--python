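import numpy as np
import pytest

from vesseg.phantom import PhantomConfig, make_dataset
from vesseg.preprocess import clip_hu, normalize_zscore
from vesseg.volumes import MaskVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_pair():
    """One 32-cube isotropic phantom (image, mask) with ~1% vessels."""
    cfg = PhantomConfig(shape=(32, 32, 32), spacing=(1, 1, 1),
                        root_radius=1.8, rng_seed=11)
    return make_dataset(cfg, 1)[0]


@pytest.fixture(scope="session")
def preprocessed_pair(small_phantom_pair):
    image, mask = small_phantom_pair
    return normalize_zscore(clip_hu(image)), mask


def random_mask(rng, shape=(12, 12, 12), p=0.2, spacing=(1, 1, 1)):
    return MaskVolume((rng.random(shape) < p).astype(np.uint8), spacing)
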