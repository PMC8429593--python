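import numpy as np
import pytest

from udclean import (
    GeneratorSpec,
    LabeledDataset,
    NoiseSpec,
    UDCConfig,
    inject_label_noise,
    make_dataset,
)


@pytest.fixture
def blobs2():
    """Small clean separable binary dataset (100/class, separation 6)."""
    return make_dataset(GeneratorSpec(C=2, n_per_class=100, dim=6, separation=6.0, seed=42))


@pytest.fixture
def blobs4():
    """Small clean separable 4-class dataset."""
    return make_dataset(GeneratorSpec(C=4, n_per_class=80, dim=8, separation=6.0, seed=43))


@pytest.fixture
def noisy_blobs2(blobs2):
    """blobs2 with symmetric 30%/30% flips plus the ground-truth record."""
    return inject_label_noise(blobs2, NoiseSpec((0.3, 0.3)), seed=7)


@pytest.fixture
def small_config():
    return UDCConfig(seed=5)


def make_separable(n_per_class=60, C=2, dim=4, separation=6.0, seed=0):
    return make_dataset(
        GeneratorSpec(C=C, n_per_class=n_per_class, dim=dim, separation=separation, seed=seed)
    )


@pytest.fixture
def tiny_manifest_df():
    import pandas as pd

    return pd.DataFrame(
        {
            "id": ["a", "b", "c", "d"],
            "f0": [0.0, 0.1, 5.0, 5.1],
            "f1": [1.0, 1.1, -1.0, -1.1],
            "label": ["cat", "cat", "dog", "dog"],
        }
    )
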