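import numpy as np
import pytest

from mfbnet.dataset import EpochedDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset(rng):
    """8 trials x 4 channels x 2 s of white noise, 2 classes."""
    data = rng.standard_normal((8, 4, 500))
    labels = np.tile([1, 2], 4)
    return EpochedDataset(data=data, labels=labels, fs=250.0)
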