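import numpy as np
import pytest

from kgcascade import SyntheticSpec, TabularDataset, generate_dataset


@pytest.fixture
def toy_dataset():
    """Small deterministic balanced dataset, no duplicates, no missing."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 4))
    y = np.tile([0, 1], 20)
    return TabularDataset(X, y, ["a", "b", "c", "d"])


@pytest.fixture
def dirty_fixture():
    """12 hand-built rows: 10 distinct, of which one has a missing cell,
    plus 2 exact duplicate copies; cleaning must leave 9 rows."""
    base = np.arange(30, dtype=float).reshape(10, 3)
    base[4, 1] = np.nan
    X = np.vstack([base, base[[0]], base[[7]]])
    y = np.array([0, 1] * 5 + [0, 1])
    return TabularDataset(X, y, ["f1", "f2", "f3"])


@pytest.fixture
def small_synthetic():
    spec = SyntheticSpec(
        n_rows=600,
        n_features=8,
        latent_rank=3,
        boundary_degree=2,
        minority_fraction=0.4,
        seed=11,
    )
    return generate_dataset(spec)
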