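"""Internal benchmark pipeline shared by the test-bed and scripts:
generate -> clean -> 80/20 split -> standard-scale -> balance."""

from __future__ import annotations

import numpy as np

from .datasets import SyntheticSpec, TabularDataset, generate_dataset
from .preprocess import (
    BalancingPlan,
    apply_balancing,
    apply_scaler,
    clean,
    fit_scaler,
    split_train_test,
)


def quadratic_benchmark(
    n_rows: int = 20_000,
    n_features: int = 20,
    latent_rank: int = 5,
    minority_fraction: float = 0.3,
    seed: int = 42,
    balance: bool = True,
) -> tuple[TabularDataset, TabularDataset]:
    """Scaled (and optionally class-balanced) train/test pair drawn from the
    quadratic-boundary low-rank generator."""
    spec = SyntheticSpec(
        n_rows=n_rows,
        n_features=n_features,
        latent_rank=latent_rank,
        boundary_degree=2,
        minority_fraction=minority_fraction,
        seed=seed,
    )
    data = clean(generate_dataset(spec))
    train, test = split_train_test(data, 0.8, (seed + 1) % 2**31)
    scaler = fit_scaler(train)
    train_s = apply_scaler(train, scaler)
    test_s = apply_scaler(test, scaler)
    if balance:
        m = int(np.bincount(train_s.labels).min())
        train_s = apply_balancing(train_s, BalancingPlan(m, seed=(seed + 2) % 2**31))
    return train_s, test_s
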