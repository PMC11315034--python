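"""Cleaning, scaling, splitting, subset partitioning and class balancing.

The balancing step mirrors the hybrid resampling used for heavily
imbalanced risk-factor data: SMOTE-style interpolation raises any class
below the per-class target m, NearMiss-style selection lowers any class
above it, so the output always has exactly m rows per class.  The target
itself is chosen by a small grid search scored on F1 of a reference linear
classifier, with the train-minus-validation F1 gap as the generalization
tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datasets import TabularDataset

__all__ = [
    "ScalerParams",
    "PartitionPlan",
    "BalancingPlan",
    "BalancingSearchResult",
    "clean",
    "fit_scaler",
    "apply_scaler",
    "split_train_test",
    "partition_subsets",
    "apply_balancing",
    "balance_search",
]


#: Default per-class target grid for survey-scale runs (hundreds of
#: thousands of rows): 50,000 to 150,000 in steps of 25,000.
FULL_SCALE_BALANCE_GRID = [50_000, 75_000, 100_000, 125_000, 150_000]


class EmptyAfterCleaningError(ValueError):
    """Every row was removed by duplicate/missing filtering."""


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature location/scale of a fitted scaler.

    ``standard``: location = column means, scale = column standard
    deviations (population, ddof=0).  ``minmax``: location = column minima,
    scale = column ranges.  Zero-scale (constant) columns transform to 0.
    """

    kind: str
    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "minmax"):
            raise ValueError(f"kind must be 'standard' or 'minmax', got {self.kind!r}")
        if np.any(self.scale < 0):
            raise ValueError("scale entries must be >= 0")


@dataclass(frozen=True)
class PartitionPlan:
    """Disjoint, exhaustive row-index lists with sizes differing by <= 1."""

    n_subsets: int
    subsets: tuple[np.ndarray, ...]
    seed: int


@dataclass(frozen=True)
class BalancingPlan:
    """Hybrid resampling target: every class ends with exactly m rows."""

    target_per_class: int
    oversampler: str = "SMOTE"
    undersampler: str = "NearMiss"
    oversampler_neighbors: int = 5
    nearmiss_version: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_per_class < 1:
            raise ValueError(f"target_per_class must be >= 1, got {self.target_per_class}")
        if self.oversampler != "SMOTE":
            raise ValueError(f"unsupported oversampler {self.oversampler!r}")
        if self.undersampler != "NearMiss":
            raise ValueError(f"unsupported undersampler {self.undersampler!r}")
        if self.nearmiss_version not in (1, 2, 3):
            raise ValueError(f"nearmiss_version must be 1, 2 or 3, got {self.nearmiss_version}")
        if self.oversampler_neighbors < 1:
            raise ValueError("oversampler_neighbors must be >= 1")


@dataclass
class BalancingSearchResult:
    grid: list[int]
    records: list[dict] = field(default_factory=list)
    chosen: BalancingPlan | None = None


def clean(data: TabularDataset) -> TabularDataset:
    """Remove exact duplicate rows (keep first), then rows with missing cells.

    Row order is preserved; drop counts are recorded in the result's
    ``metadata`` under ``n_duplicates_dropped`` / ``n_missing_dropped``.
    """
    if data.n_rows == 0:
        raise ValueError("dataset is empty")
    frame = data.to_frame()
    dedup = frame.drop_duplicates(keep="first")
    n_dup = len(frame) - len(dedup)
    complete = dedup.dropna()
    n_miss = len(dedup) - len(complete)
    if len(complete) == 0:
        raise EmptyAfterCleaningError("all rows removed: empty after cleaning")
    out = TabularDataset.from_frame(complete.reset_index(drop=True), data.label_name)
    out.metadata["n_duplicates_dropped"] = n_dup
    out.metadata["n_missing_dropped"] = n_miss
    return out


def fit_scaler(data: TabularDataset, kind: str = "standard") -> ScalerParams:
    if np.isnan(data.features).any():
        raise ValueError("missing cells present: run clean() before fitting a scaler")
    X = data.features
    if kind == "standard":
        return ScalerParams(kind, X.mean(axis=0), X.std(axis=0))
    if kind == "minmax":
        lo = X.min(axis=0)
        return ScalerParams(kind, lo, X.max(axis=0) - lo)
    raise ValueError(f"kind must be 'standard' or 'minmax', got {kind!r}")


def apply_scaler(data: TabularDataset, scaler: ScalerParams) -> TabularDataset:
    if data.n_features != len(scaler.location):
        raise ValueError(
            f"dataset has {data.n_features} columns, scaler expects {len(scaler.location)}"
        )
    safe = np.where(scaler.scale > 0, scaler.scale, 1.0)
    X = (data.features - scaler.location) / safe
    X[:, scaler.scale == 0] = 0.0
    return TabularDataset(X, data.labels.copy(), list(data.feature_names), data.label_name)


def split_train_test(
    data: TabularDataset, train_fraction: float, seed: int
) -> tuple[TabularDataset, TabularDataset]:
    """Seeded uniform shuffle; first floor(f*n) rows to train."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = data.n_rows
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty split for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return data.select_rows(perm[:n_train]), data.select_rows(perm[n_train:])


def partition_subsets(data: TabularDataset, n_subsets: int, seed: int) -> PartitionPlan:
    """Seeded shuffle, round-robin assignment into equal-size subsets.

    Subset sizes differ by at most one; within each subset indices are
    sorted ascending so row order inside a subset matches the input.
    """
    n = data.n_rows
    if not 1 <= n_subsets <= n:
        raise ValueError(f"n_subsets must be in [1, {n}], got {n_subsets}")
    perm = np.random.default_rng(seed).permutation(n)
    subsets = tuple(np.sort(perm[i::n_subsets]) for i in range(n_subsets))
    return PartitionPlan(n_subsets, subsets, seed)


def _smote_synthesize(
    X: np.ndarray, n_new: int, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    """Interpolate n_new points between class members and their within-class
    nearest neighbors."""
    n = len(X)
    if n < k_neighbors + 1:
        raise ValueError(
            f"SMOTE with {k_neighbors} neighbors needs at least "
            f"{k_neighbors + 1} class members, got {n}"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbors = idx[:, 1:]  # drop self
    base = rng.integers(0, n, size=n_new)
    pick = neighbors[base, rng.integers(0, k_neighbors, size=n_new)]
    gap = rng.random((n_new, 1))
    return X[base] + gap * (X[pick] - X[base])


def _nearmiss_select(
    X_major: np.ndarray, X_minor: np.ndarray, m: int, version: int
) -> np.ndarray:
    """Indices of m majority rows kept by the NearMiss criterion.

    Version 1 keeps those with the smallest mean distance to their 3
    closest minority samples; version 2 uses the 3 farthest minority
    samples; version 3 first short-lists majority rows that are nearest
    neighbors of minority rows, then keeps those with the largest mean
    distance to their 3 closest minority samples.
    """
    k = min(3, len(X_minor))
    nn = NearestNeighbors(n_neighbors=k).fit(X_minor)
    near_mean = nn.kneighbors(X_major)[0].mean(axis=1)
    if version == 1:
        order = np.argsort(near_mean, kind="stable")
    elif version == 2:
        # mean distance to the k farthest minority samples, chunked to bound memory
        crit = np.empty(len(X_major))
        for start in range(0, len(X_major), 2048):
            block = X_major[start : start + 2048]
            dist = np.sqrt(
                np.maximum(
                    (block**2).sum(1)[:, None]
                    - 2 * block @ X_minor.T
                    + (X_minor**2).sum(1)[None, :],
                    0.0,
                )
            )
            far = np.partition(dist, len(X_minor) - k, axis=1)[:, len(X_minor) - k :]
            crit[start : start + 2048] = far.mean(axis=1)
        order = np.argsort(crit, kind="stable")
    else:
        nn_maj = NearestNeighbors(n_neighbors=min(3, len(X_major))).fit(X_major)
        shortlist = np.unique(nn_maj.kneighbors(X_minor)[1].ravel())
        ranked = shortlist[np.argsort(-near_mean[shortlist], kind="stable")]
        rest = np.setdiff1d(np.arange(len(X_major)), shortlist, assume_unique=False)
        order = np.concatenate([ranked, rest[np.argsort(near_mean[rest], kind="stable")]])
    return np.sort(order[:m])


def apply_balancing(train: TabularDataset, plan: BalancingPlan) -> TabularDataset:
    """Resample every class to exactly ``plan.target_per_class`` rows.

    Classes below the target are raised by SMOTE interpolation between
    seeded nearest neighbors; classes above it are lowered by NearMiss
    selection.  The output has exactly 2m rows, m per class, in seeded
    shuffled order.
    """
    if np.isnan(train.features).any():
        raise ValueError("missing cells present: run clean() before balancing")
    classes = np.unique(train.labels)
    if len(classes) != 2:
        raise ValueError(f"balancing needs both classes present, found {classes}")
    m = plan.target_per_class
    rng = np.random.default_rng(plan.seed)

    parts_X, parts_y = [], []
    for c in classes:
        Xc = train.features[train.labels == c]
        other = train.features[train.labels != c]
        if len(Xc) < m:
            synth = _smote_synthesize(Xc, m - len(Xc), plan.oversampler_neighbors, rng)
            Xc = np.vstack([Xc, synth])
        elif len(Xc) > m:
            keep = _nearmiss_select(Xc, other, m, plan.nearmiss_version)
            Xc = Xc[keep]
        parts_X.append(Xc)
        parts_y.append(np.full(m, c))

    X = np.vstack(parts_X)
    y = np.concatenate(parts_y)
    perm = rng.permutation(len(y))
    return TabularDataset(X[perm], y[perm], list(train.feature_names), train.label_name)


def balance_search(
    train: TabularDataset,
    grid: list[int],
    plan_template: BalancingPlan | None = None,
    eval_seed: int = 0,
) -> BalancingSearchResult:
    """Pick the per-class target m from a grid by validation F1.

    For each candidate m the 80% fit-portion of ``train`` is balanced to m
    per class, a reference linear SGD classifier (the cascade base learner
    configuration) is fitted on it, and macro F1 is recorded on the
    balanced rows and on the untouched 20% validation portion of the
    original, unbalanced train.  The chosen m maximizes validation F1;
    ties break by smaller |train F1 - validation F1|, then by smaller m.
    """
    from .cascade import CascadeConfig, make_base_learner
    from .evaluate import compute_metrics

    if not grid:
        raise ValueError("grid must be nonempty")
    if sorted(grid) != list(grid):
        raise ValueError("grid must be sorted ascending")
    if plan_template is None:
        plan_template = BalancingPlan(target_per_class=grid[0], seed=eval_seed)

    fit_part, val_part = split_train_test(train, 0.8, eval_seed)
    result = BalancingSearchResult(grid=list(grid))
    failures = 0
    for m in grid:
        plan = replace(plan_template, target_per_class=m)
        try:
            balanced = apply_balancing(fit_part, plan)
            clf = make_base_learner(CascadeConfig(n_levels=1, seed=eval_seed), eval_seed)
            clf.fit(balanced.features, balanced.labels)
            train_f1 = compute_metrics(
                balanced.labels, clf.predict(balanced.features), "macro"
            ).f1
            val_f1 = compute_metrics(
                val_part.labels, clf.predict(val_part.features), "macro"
            ).f1
            result.records.append(
                {
                    "m": m,
                    "train_f1": train_f1,
                    "validation_f1": val_f1,
                    "gap": train_f1 - val_f1,
                    "failed": False,
                }
            )
        except ValueError as exc:
            failures += 1
            result.records.append({"m": m, "failed": True, "error": str(exc)})
    if failures == len(grid):
        raise ValueError("balancing failed for every grid value")

    ok = [r for r in result.records if not r["failed"]]
    best = min(ok, key=lambda r: (-r["validation_f1"], abs(r["gap"]), r["m"]))
    result.chosen = replace(plan_template, target_per_class=best["m"])
    return result
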