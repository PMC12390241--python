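import numpy as np
import pytest

import mrmbench as mb


@pytest.fixture(scope="session")
def paper_phantom():
    """Full-size 512-px phantom with default ROIs (supersample 8)."""
    return mb.make_phantom_with_rois(n=512, supersample=8)


@pytest.fixture(scope="session")
def small_phantom():
    """128-px phantom used for reduced-scale end-to-end runs."""
    return mb.make_phantom_with_rois(n=128, supersample=8, roi_side=16)


@pytest.fixture(scope="session")
def small_kspace(small_phantom):
    return mb.image_to_kspace(small_phantom.image)


@pytest.fixture(scope="session")
def paper_kspace(paper_phantom):
    return mb.image_to_kspace(paper_phantom.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
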