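"""Per-level feature machinery: quadratic Kolmogorov-Gabor expansion and
variance-threshold PCA with reusable fitted transforms.

A quadratic Kolmogorov-Gabor polynomial over d inputs produces all linear
terms plus every pairwise product x_i * x_j with i <= j (squares included),
d + d(d+1)/2 columns in total.  The constant term is deliberately excluded:
it has zero variance, would be destroyed by PCA centering, and the linear
classifier's intercept carries it anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KGExpansionSpec",
    "PCAReducer",
    "kg_expand_spec",
    "kg_expand",
    "fit_pca_reducer",
    "apply_pca",
]


@dataclass(frozen=True)
class KGExpansionSpec:
    """Ordered term list of the quadratic expansion for a given input width.

    ``terms`` lists index tuples: first the d singletons ``(i,)``, then all
    pairs ``(i, j)`` with ``i <= j`` in lexicographic order.  The order is
    fixed so that serialized models are portable.
    """

    input_dim: int
    terms: tuple[tuple[int, ...], ...]
    output_dim: int


def kg_expand_spec(input_dim: int) -> KGExpansionSpec:
    if input_dim < 1:
        raise ValueError(f"input_dim must be >= 1, got {input_dim}")
    terms: list[tuple[int, ...]] = [(i,) for i in range(input_dim)]
    terms += [(i, j) for i in range(input_dim) for j in range(i, input_dim)]
    return KGExpansionSpec(
        input_dim=input_dim,
        terms=tuple(terms),
        output_dim=input_dim + input_dim * (input_dim + 1) // 2,
    )


def kg_expand(X: np.ndarray, spec: KGExpansionSpec) -> np.ndarray:
    """Evaluate the expansion column-wise: singleton terms copy the input
    column, pair terms multiply the two named columns elementwise."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(
            f"input has shape {X.shape}, expected (n, {spec.input_dim})"
        )
    d = spec.input_dim
    pairs = spec.terms[d:]
    i_idx = np.fromiter((p[0] for p in pairs), dtype=int, count=len(pairs))
    j_idx = np.fromiter((p[1] for p in pairs), dtype=int, count=len(pairs))
    return np.hstack([X, X[:, i_idx] * X[:, j_idx]])


@dataclass
class PCAReducer:
    """A fitted centering + orthonormal projection selected to a variance
    threshold.

    ``components`` is a k x m matrix with orthonormal rows;
    ``explained_variance_ratios`` are the corresponding fractions of total
    variance, non-increasing; k is the smallest count whose cumulative
    ratio reaches ``variance_threshold`` (capped at the rank of the
    centered training matrix).
    """

    input_dim: int
    center: np.ndarray
    components: np.ndarray
    explained_variance_ratios: np.ndarray
    variance_threshold: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca_reducer(X: np.ndarray, variance_threshold: float = 0.95) -> PCAReducer:
    """Fit a PCA reducer retaining the minimal leading component set whose
    cumulative explained-variance ratio reaches the threshold.

    Uses a thin SVD of the centered matrix; sample covariance uses the
    n - 1 denominator (ratios are scale-free either way).  A zero-variance
    matrix yields a k = 0 reducer (transform maps to empty width) with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, m = X.shape
    if n < 2:
        raise ValueError(f"PCA needs at least 2 rows, got {n}")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )

    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    if total <= 0:
        warnings.warn("zero-variance matrix: reducer retains 0 components")
        return PCAReducer(m, center, np.empty((0, m)), np.empty(0), variance_threshold)

    # numerical rank of the centered matrix
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps))
    ratios = variances / total
    cumulative = np.cumsum(ratios)
    # smallest k with cumulative ratio >= threshold (tolerant at equality)
    k = int(np.argmax(cumulative >= variance_threshold - 1e-12)) + 1
    if cumulative[-1] < variance_threshold - 1e-12:
        k = len(ratios)
    k = min(k, rank)
    k = max(k, 1) if rank >= 1 else 0

    return PCAReducer(
        input_dim=m,
        center=center,
        components=Vt[:k].copy(),
        explained_variance_ratios=ratios[:k].copy(),
        variance_threshold=variance_threshold,
    )


def apply_pca(X: np.ndarray, reducer: PCAReducer) -> np.ndarray:
    """Project onto the stored components; never refits."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != reducer.input_dim:
        raise ValueError(
            f"input has shape {X.shape}, expected (n, {reducer.input_dim})"
        )
    return (X - reducer.center) @ reducer.components.T
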