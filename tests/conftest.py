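import numpy as np
import pandas as pd
import pytest

from plscova.simulate import simulate_joint_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Moderate-SNR planted rank-1 dataset shared across tests."""
    return simulate_joint_dataset(
        n=150, p_snps=60, p_transcripts=40, q_features=7,
        n_components=1, effect_sizes=[3.0], noise_sd=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def null_dataset():
    """No planted association between the genetic and phenotype blocks."""
    return simulate_joint_dataset(
        n=120, p_snps=40, p_transcripts=30, q_features=5,
        n_components=1, effect_sizes=[0.0], noise_sd=1.0,
        confounding=False, seed=12,
    )


@pytest.fixture
def standardized_pair():
    """Small standardised block pair with a built-in association."""
    rng = np.random.default_rng(21)
    n, p, q = 80, 12, 4
    z = rng.normal(size=n)
    X = rng.normal(size=(n, p)) + np.outer(z, rng.normal(size=p))
    Y = rng.normal(size=(n, q)) + np.outer(z, rng.normal(size=q))
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    return Xs, Ys
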