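"""Shared fixtures: small synthetic datasets and trained models.

Everything is generated programmatically at run time with fixed seeds; the
expensive fixtures (trained networks) are session-scoped and deliberately
small so the whole suite stays CPU-friendly.
"""

import pytest

from fiberchi import (ChiGrid, CorruptionConfig, LabelRanges, OrientationParams,
                      build_dataset, sample_labels, train_fcnn, TrainConfig)


@pytest.fixture
def grid():
    return ChiGrid(360)


@pytest.fixture
def params():
    """A generic two-group parameter set (canonical: gamma1 >= gamma2)."""
    return OrientationParams(10.0, 5.0, 40.0, 30.0, -20.0, 8.0, -50.0, 60.0, 2.0)


def random_params(rng, n=1):
    """Random canonical parameter rows for property tests."""
    return sample_labels(n, LabelRanges(), seed=int(rng.integers(2**31)))


@pytest.fixture(scope="session")
def small_clean_dataset():
    """3000 clean (uncorrupted) curves, split 0.8/0.1/0.1."""
    labels = sample_labels(3000, seed=11)
    return build_dataset(labels, ChiGrid(360), None, seed=11, keep_clean=True)


@pytest.fixture(scope="session")
def small_corrupted_dataset():
    """3000 corrupted curves (Poisson + 0.3 masking + scaling)."""
    labels = sample_labels(3000, seed=11)
    return build_dataset(labels, ChiGrid(360), CorruptionConfig(seed=11),
                         seed=11, keep_clean=True)


_TINY_TRAIN = TrainConfig(hidden_layer_sizes=(256, 128), max_epochs=40,
                          patience=10, seed=3)


@pytest.fixture(scope="session")
def fcnn_masked(small_corrupted_dataset):
    """FCNN trained on corrupted curves (the masked-training strategy)."""
    return train_fcnn(small_corrupted_dataset, _TINY_TRAIN)


@pytest.fixture(scope="session")
def fcnn_clean(small_clean_dataset):
    """FCNN trained on clean curves only (no corruption)."""
    return train_fcnn(small_clean_dataset, _TINY_TRAIN)
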