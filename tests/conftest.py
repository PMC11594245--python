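import numpy as np
import pytest

from protods import (
    NetworkConfig,
    SignatureModel,
    SimConfig,
    dataset_to_records,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated binary dataset, small cubes: 12 train / 6 test per class."""
    model = SignatureModel(n_classes=2, n_bands=64)
    cfg = SimConfig(
        seed=7, n_majority=12, n_minority=(12,), n_test_per_class=6,
        height=6, width=6,
    )
    ds = simulate_dataset(model, cfg)
    train, test, band_idx = dataset_to_records(ds)
    return ds, train, test, band_idx


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return NetworkConfig(input_dim=48, hidden_dim=32, n_blocks=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
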