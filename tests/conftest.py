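import numpy as np
import pytest

from leukoseg import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dark_smear():
    """A dark, low-contrast smear with its mask (enhancement fixture)."""
    spec = synthdata.SyntheticSmearSpec(
        canvas_size=(128, 128), n_cells=2,
        background_brightness_range=(70, 90), noise_sigma=3.0, seed=5)
    img, mask = synthdata.generate_smear(spec)
    # compress dynamic range to emulate under-exposed acquisition
    img = (img * 0.5 + 40).astype(np.uint8)
    return img, mask


@pytest.fixture(scope="session")
def small_smear():
    spec = synthdata.SyntheticSmearSpec(canvas_size=(128, 128), n_cells=2, seed=7)
    return synthdata.generate_smear(spec)
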