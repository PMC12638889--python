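import numpy as np
import pytest

from cootseg.otsu import compute_histogram
from cootseg.synthetic import synth_multimodal_image, synth_two_delta_image


@pytest.fixture(scope="session")
def two_delta_image():
    return synth_two_delta_image(0, 255, 64, 64)


@pytest.fixture(scope="session")
def three_mode_image():
    """Default three-mode banded Gaussian-mixture image (128x128, seed 0)."""
    return synth_multimodal_image(seed=0)


@pytest.fixture(scope="session")
def two_delta_hist(two_delta_image):
    return compute_histogram(two_delta_image)


@pytest.fixture(scope="session")
def three_mode_hist(three_mode_image):
    return compute_histogram(three_mode_image)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
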