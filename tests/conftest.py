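import numpy as np
import pytest

from atlasoverlap.atlas_model import LabelVolume, generic_terminology


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_label_volume(rng, dims=(12, 10, 8), n_labels=4):
    labels = rng.integers(0, n_labels + 1, size=dims).astype(np.int32)
    return LabelVolume(labels, 39.0, generic_terminology(range(1, n_labels + 1)))


@pytest.fixture
def small_volume(rng):
    return random_label_volume(rng)


@pytest.fixture
def two_block_volume():
    """Deterministic 8x8x8 volume: label 1 in the left half, 2 in the right."""
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[:4] = 1
    labels[4:] = 2
    return LabelVolume(labels, 39.0, generic_terminology([1, 2]))
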