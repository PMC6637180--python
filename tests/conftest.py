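"""Shared fixtures: synthetic datasets and trained models.

The standard-scale dataset (50 samples x 200 features x 30 metabolites,
noise sd 0.05) and the model trained on it are session-scoped because
training is the expensive step and several behavioural tests interrogate
the same fit.
"""

import numpy as np
import pandas as pd
import pytest

from micromet import (AbundanceTable, TrainConfig, generate, train_all)


@pytest.fixture(scope="session")
def dataset():
    """Standard-scale synthetic training dataset with planted signal."""
    return generate(n_samples=50, n_features=200, n_metabolites=30,
                    frac_planted=0.67, support_size=8, noise_sd=0.05, seed=1)


@pytest.fixture(scope="session")
def trained_model(dataset):
    """Elastic-net models trained on the standard dataset (10-fold CV)."""
    return train_all(dataset.X, dataset.Y, TrainConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast-to-train dataset for smoke and determinism tests."""
    return generate(n_samples=30, n_features=60, n_metabolites=8,
                    frac_planted=0.75, support_size=5, noise_sd=0.05, seed=7)


@pytest.fixture
def tiny_table():
    """3 samples x 3 features with simple values."""
    return AbundanceTable(pd.DataFrame(
        [[1.0, 1.0, 2.0], [2.0, 2.0, 4.0], [4.0, 0.0, 4.0]],
        index=["s1", "s2", "s3"], columns=["f1", "f2", "f3"]))


def make_table(values, prefix_s="s", prefix_f="f", normalized=False):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix_s}{i}" for i in range(values.shape[0])],
        columns=[f"{prefix_f}{j}" for j in range(values.shape[1])])
    return AbundanceTable(df, is_normalized=normalized)
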