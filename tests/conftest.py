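import numpy as np
import pytest

from pdfftexture.io_maps import PDFFVolume, ROIMask
from pdfftexture.preprocess import quantize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    data = rng.uniform(0, 100, size=(10, 10, 10))
    return PDFFVolume(data=data, spacing=(1.5, 1.5, 1.5))


@pytest.fixture
def small_mask(small_volume, rng):
    labels = np.zeros(small_volume.shape, dtype=np.int16)
    labels[2:8, 2:8, 2:8] = 1
    return ROIMask(labels=labels, label_table={1: "PS_left"},
                   spacing=small_volume.spacing)


def qroi_from_levels(levels3d, n_levels):
    """QuantizedROI built directly from a dense level array (0 = background)."""
    levels3d = np.asarray(levels3d)
    idx = np.argwhere(levels3d > 0)
    width = 100.0 / n_levels
    values = (levels3d[tuple(idx.T)] - 0.5) * width  # bin centers
    return quantize(values, idx, n_levels=n_levels, shape=levels3d.shape)
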