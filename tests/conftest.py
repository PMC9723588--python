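import numpy as np
import pytest

from lakebrowning.metrics import bray_curtis
from lakebrowning.simulate import simulate_dataset
from lakebrowning.surface import (
    build_pair_dataset,
    fit_gradient_boost,
    predict_meshgrid,
    split_train_test,
)


@pytest.fixture(scope="session")
def standard_dataset():
    """One standard-scenario dataset shared across read-only tests."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def standard_surface(standard_dataset):
    """Fitted GBT surface on the standard scenario (expensive, share it)."""
    ds = standard_dataset
    g = ds.sites["gradient_value"].to_numpy()
    pairs = build_pair_dataset(g, bray_curtis(ds.counts))
    train, test = split_train_test(pairs, 0.8, seed=11)
    gbt = fit_gradient_boost(train, seed=11)
    mesh = predict_meshgrid(gbt, g, max_grid=300)
    return {"gradient": g, "pairs": pairs, "train": train, "test": test,
            "gbt": gbt, "mesh": mesh}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
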