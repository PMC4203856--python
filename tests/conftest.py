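import numpy as np
import pytest

from casam.synthetic import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_030():
    """One deterministic phantom with 30% dense fraction."""
    return generate_phantom(PhantomConfig(dense_fraction=0.30), seed=42)


@pytest.fixture(scope="session")
def segmented_030(phantom_030):
    from casam.segmentation import segment_mammogram

    img, truth = phantom_030
    return segment_mammogram(img), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
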