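"""Synthetic tabular datasets and the in-memory container they flow through.

The generator emulates the statistical shape of a large behavioural-risk
survey extract used for binary disease-risk classification: many correlated
numeric features that are compressible by PCA (a low-rank latent factor
structure), a nonlinear (polynomial) class boundary in the latent space,
strong class imbalance, plus optional exact-duplicate rows and missing
cells so the cleaning stage has something to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "TabularDataset",
    "generate_dataset",
    "corrupt_dataset",
    "read_csv",
    "write_csv",
]

#: Standard deviation of the isotropic observation noise added on top of the
#: latent mixing; small relative to the unit-variance latent factors so the
#: observed covariance keeps ~latent_rank dominant directions.
OBSERVATION_NOISE_SD = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic binary-classification dataset.

    ``n_features`` observed columns are linear mixes of ``latent_rank``
    independent standard-normal factors; the true label is the sign of a
    random polynomial of degree ``boundary_degree`` in the latent factors,
    thresholded at a quantile so the positive class hits
    ``minority_fraction``, then flipped with probability ``label_noise``.
    """

    n_rows: int
    n_features: int
    latent_rank: int
    boundary_degree: int = 2
    minority_fraction: float = 0.08
    label_noise: float = 0.0
    duplicate_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be positive, got {self.n_rows}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be positive, got {self.n_features}")
        if not 1 <= self.latent_rank <= self.n_features:
            raise ValueError(
                f"latent_rank must be in [1, n_features={self.n_features}], "
                f"got {self.latent_rank}"
            )
        if self.boundary_degree < 1:
            raise ValueError(f"boundary_degree must be >= 1, got {self.boundary_degree}")
        if not 0.0 < self.minority_fraction <= 0.5:
            raise ValueError(
                f"minority_fraction must be in (0, 0.5], got {self.minority_fraction}"
            )
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(f"label_noise must be in [0, 0.5), got {self.label_noise}")
        if not 0.0 <= self.duplicate_fraction < 0.5:
            raise ValueError(
                f"duplicate_fraction must be in [0, 0.5), got {self.duplicate_fraction}"
            )
        if not 0.0 <= self.missing_fraction < 0.5:
            raise ValueError(
                f"missing_fraction must be in [0, 0.5), got {self.missing_fraction}"
            )
        if self.minority_fraction + self.label_noise >= 1.0:
            raise ValueError("minority_fraction + label_noise must be < 1")


@dataclass
class TabularDataset:
    """A feature matrix with binary labels and column names.

    Missing feature cells are NaN (an empty field in CSV); labels are never
    missing. ``metadata`` carries provenance such as cleaning counts and is
    not part of equality.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    label_name: str = "label"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"row count {self.features.shape[0]} != label count {self.labels.shape[0]}"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"column count {self.features.shape[1]} != "
                f"feature_names length {len(self.feature_names)}"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if any(not n for n in self.feature_names):
            raise ValueError("feature_names must be non-empty strings")
        lab = np.unique(self.labels)
        if not np.isin(lab, [0, 1]).all():
            raise ValueError(f"labels must be binary 0/1, found values {lab}")
        self.labels = self.labels.astype(int)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            self.features.copy(),
            self.labels.copy(),
            list(self.feature_names),
            self.label_name,
            dict(self.metadata),
        )

    def select_rows(self, index: Sequence[int] | np.ndarray) -> "TabularDataset":
        index = np.asarray(index)
        return TabularDataset(
            self.features[index],
            self.labels[index],
            list(self.feature_names),
            self.label_name,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame[self.label_name] = self.labels
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_name: str) -> "TabularDataset":
        if label_name not in frame.columns:
            raise ValueError(f"label column {label_name!r} not found in CSV header")
        feature_names = [c for c in frame.columns if c != label_name]
        return cls(
            frame[feature_names].to_numpy(dtype=float),
            frame[label_name].to_numpy(),
            feature_names,
            label_name,
        )


def _monomial_exponents(rank: int, degree: int) -> np.ndarray:
    """All exponent vectors over ``rank`` variables with total degree 1..degree."""
    out: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int, budget: int) -> None:
        if remaining == 0:
            if sum(prefix) >= 1:
                out.append(prefix)
            return
        for e in range(budget + 1):
            rec(prefix + (e,), remaining - 1, budget - e)

    rec((), rank, degree)
    return np.array(out, dtype=int)


def generate_dataset(spec: SyntheticSpec) -> TabularDataset:
    """Draw one dataset from the low-rank latent-factor model in ``spec``.

    Deterministic for a fixed spec: the same seed yields an identical
    matrix and label vector.  The quantile threshold on the boundary
    polynomial is compensated for label noise so that the realized positive
    fraction matches ``minority_fraction`` in expectation even after flips.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, r = spec.n_rows, spec.n_features, spec.latent_rank

    latent = rng.standard_normal((n, r))
    mixing = rng.standard_normal((r, d))
    X = latent @ mixing + OBSERVATION_NOISE_SD * rng.standard_normal((n, d))

    exponents = _monomial_exponents(r, spec.boundary_degree)
    coef = rng.standard_normal(len(exponents))
    # score_i = sum_m coef_m * prod_k Z_ik^e_mk
    score = np.ones((n, len(exponents)))
    for k in range(r):
        e = exponents[:, k]
        nz = e > 0
        if nz.any():
            score[:, nz] *= latent[:, [k]] ** e[nz]
    score = score @ coef

    # Flips move the rate toward 1/2; aim the pre-flip rate so the post-flip
    # expectation equals the requested minority fraction.
    nu = spec.label_noise
    p_clean = (spec.minority_fraction - nu) / (1.0 - 2.0 * nu)
    p_clean = min(max(p_clean, 0.0), 1.0)
    threshold = np.quantile(score, 1.0 - p_clean) if p_clean > 0 else np.inf
    y = (score > threshold).astype(int)
    if nu > 0:
        flips = rng.random(n) < nu
        y = np.where(flips, 1 - y, y)

    names = [f"x{i + 1}" for i in range(d)]
    data = TabularDataset(X, y, names)
    if spec.duplicate_fraction > 0 or spec.missing_fraction > 0:
        data = corrupt_dataset(
            data,
            spec.duplicate_fraction,
            spec.missing_fraction,
            seed=int(rng.integers(2**31)),
        )
    data.metadata["spec"] = dataclasses.asdict(spec)
    return data


def corrupt_dataset(
    data: TabularDataset,
    duplicate_fraction: float,
    missing_fraction: float,
    seed: int,
) -> TabularDataset:
    """Return a copy with exact duplicate rows appended and feature cells blanked.

    ``floor(missing_fraction * n * d)`` cells of the original rows are set to
    NaN first; ``floor(duplicate_fraction * n)`` rows are then copied verbatim
    (features and label) and appended, so every appended row is an exact
    duplicate of an earlier one.  Labels are never blanked.
    """
    if not 0.0 <= duplicate_fraction < 0.5:
        raise ValueError(f"duplicate_fraction must be in [0, 0.5), got {duplicate_fraction}")
    if not 0.0 <= missing_fraction < 0.5:
        raise ValueError(f"missing_fraction must be in [0, 0.5), got {missing_fraction}")

    rng = np.random.default_rng(seed)
    n, d = data.features.shape
    X = data.features.copy()
    y = data.labels.copy()

    n_missing = int(np.floor(missing_fraction * n * d))
    if n_missing:
        cells = rng.choice(n * d, size=n_missing, replace=False)
        X[np.unravel_index(cells, (n, d))] = np.nan

    n_dup = int(np.floor(duplicate_fraction * n))
    if n_dup:
        src = rng.integers(0, n, size=n_dup)
        X = np.vstack([X, X[src]])
        y = np.concatenate([y, y[src]])

    return TabularDataset(X, y, list(data.feature_names), data.label_name)


def write_csv(data: TabularDataset, path) -> None:
    """Write as headered CSV, label column last, missing cells empty."""
    data.to_frame().to_csv(path, index=False, na_rep="")


def read_csv(path, label_name: str = "label") -> TabularDataset:
    return TabularDataset.from_frame(pd.read_csv(path), label_name)
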