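import itertools

import numpy as np
import pytest

from threetrees import make_setting, split_within_cluster


@pytest.fixture(scope="session")
def m1_split():
    """One M1 (linear, high ICC, high correlation) dataset, split 50/50."""
    data, params = make_setting("M1", "high", "high", 70, 50, seed=11)
    train, test = split_within_cluster(data, 0.5, seed=12)
    return data, params, train, test


@pytest.fixture(scope="session")
def m2_split():
    """One M2 (semilinear with interaction) dataset, split 50/50."""
    data, params = make_setting("M2", "high", "high", 70, 50, seed=21)
    train, test = split_within_cluster(data, 0.5, seed=22)
    return data, params, train, test


def xor_dataset(seed, n_per_cell=15, signal=3.0, noise=0.1):
    """Two binary covariates, target high on the off-diagonal cells.

    No single split has positive expected gain, so greedy engines stall at
    the root while a global search can recover the 4-cell partition.
    """
    rng = np.random.default_rng(seed)
    cells = np.array(list(itertools.product([0, 1], [0, 1])) * n_per_cell)
    X = cells.astype(float)
    y = np.logical_xor(cells[:, 0], cells[:, 1]).astype(float) * signal
    return X, y + rng.normal(0.0, noise, len(y))
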