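import numpy as np
import pandas as pd
import pytest

from greyhound.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic dataset shared by decay/model tests."""
    cfg = SimConfig(
        n_genes=80,
        length_range=(60, 120),
        n_rbps=20,
        latent_rank=3,
        seed=7,
    )
    truth, counts = simulate_dataset(cfg, depth=200.0)
    return truth, counts


@pytest.fixture(scope="session")
def toy_counts():
    """Hand-written conversion-count table for exact filter checks."""
    rows = [
        # gene, sample, replicate, n_T, n_TC
        ("g1", "c1", "r1", 100, 0),
        ("g1", "c1", "r2", 100, 4),
        ("g1", "c2", "r1", 50, 5),
        ("g1", "c2", "r2", 50, 5),
        ("g2", "c1", "r1", 9, 1),   # below min coverage even pooled? 9+0=9
        ("g2", "c1", "r2", 0, 0),
        ("g2", "c2", "r1", 200, 20),
        ("g2", "c2", "r2", 200, 10),
        ("g3", "c1", "r1", 40, 2),
        ("g3", "c1", "r2", 60, 3),
        ("g3", "c2", "r1", 80, 8),
        ("g3", "c2", "r2", 20, 2),
    ]
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "n_T", "n_TC"])


@pytest.fixture(scope="session")
def toy_expression():
    return pd.DataFrame(
        {"c1": [10.0, 5.0, 2.0], "c2": [20.0, 5.0, 4.0]},
        index=["g1", "g2", "g3"],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
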