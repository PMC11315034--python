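"""Evaluation harness: precision/recall/F1, the depth-scan experiment with
generalization-gap depth selection, and the four-method comparison.

Plain accuracy is deliberately absent: the target problems are strongly
imbalanced, where accuracy is uninformative.  The default averaging is
macro (unweighted mean over the two classes), which is robust to the
imbalance of the test set; positive-class and weighted averaging are
available.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .cascade import (
    CascadeConfig,
    CascadeFitError,
    CascadeModel,
    fit_cascade,
    make_base_learner,
    predict_cascade,
)
from .datasets import TabularDataset
from .features import kg_expand, kg_expand_spec

__all__ = [
    "ClassMetrics",
    "DepthScanResult",
    "ComparisonReport",
    "compute_metrics",
    "depth_scan",
    "compare_methods",
]

#: Refuse to materialize quadratic expansions wider than this many columns.
DEFAULT_EXPANSION_CAP = 50_000

DEFAULT_SGD_GRID = {"alpha": [1e-5, 1e-4, 1e-3]}


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    averaging: str


@dataclass
class DepthScanResult:
    depths: list[int]
    records: list[dict] = field(default_factory=list)
    chosen_depth: int | None = None
    overfit_flags: list[int] = field(default_factory=list)


@dataclass
class ComparisonReport:
    """Per-method train/test metrics, fit time and mean classifier input
    width for plain SGD, SGD on the full quadratic expansion, the cascade
    without PCA reduction, and the PCA-reduced cascade."""

    methods: dict[str, dict] = field(default_factory=dict)


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, averaging: str = "macro"
) -> ClassMetrics:
    """Precision, recall and F1 from the confusion matrix.

    ``macro``: unweighted mean of the per-class values over both classes;
    ``positive``: the positive (label 1) class only; ``weighted``:
    support-weighted mean.  Zero denominators yield 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty input")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(np.unique(arr), [0, 1]).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    if averaging not in ("macro", "positive", "weighted"):
        raise ValueError(f"unknown averaging {averaging!r}")

    sk_avg = "binary" if averaging == "positive" else averaging
    p, r, f, _ = precision_recall_fscore_support(
        y_true,
        y_pred,
        average=sk_avg,
        labels=[0, 1] if sk_avg != "binary" else None,
        pos_label=1,
        zero_division=0,
    )
    if averaging == "positive" and (y_pred == 1).sum() == 0:
        warnings.warn("no positive predictions: precision set to 0")
    return ClassMetrics(float(p), float(r), float(f), averaging)


def _eval_model(model: CascadeModel, data: TabularDataset, averaging: str) -> ClassMetrics:
    return compute_metrics(data.labels, predict_cascade(model, data.features), averaging)


def depth_scan(
    train: TabularDataset,
    test: TabularDataset,
    depths: list[int],
    config: CascadeConfig,
    averaging: str = "macro",
) -> DepthScanResult:
    """Fit one cascade per candidate depth (shared seed) and select the depth
    maximizing test F1, ties broken by smaller |train-test F1 gap| then
    smaller depth.  Depths where test F1 exceeds train F1 are flagged as
    overfitting-pattern depths; infeasible depths are recorded as failed
    and excluded from selection.
    """
    if not depths or any(d < 1 for d in depths):
        raise ValueError("depths must be nonempty with every entry >= 1")
    result = DepthScanResult(depths=list(depths))
    for depth in depths:
        cfg = replace(config, n_levels=depth)
        t0 = time.perf_counter()
        try:
            model = fit_cascade(train, cfg)
        except (CascadeFitError, ValueError) as exc:
            result.records.append({"depth": depth, "failed": True, "error": str(exc)})
            continue
        fit_seconds = time.perf_counter() - t0
        tr = _eval_model(model, train, averaging)
        te = _eval_model(model, test, averaging)
        result.records.append(
            {
                "depth": depth,
                "failed": False,
                "train": tr,
                "test": te,
                "gap": tr.f1 - te.f1,
                "fit_seconds": fit_seconds,
                "per_level_components": model.metadata["per_level_components"],
            }
        )
        if te.f1 > tr.f1:
            result.overfit_flags.append(depth)
    ok = [r for r in result.records if not r["failed"]]
    if ok:
        best = min(ok, key=lambda r: (-r["test"].f1, abs(r["gap"]), r["depth"]))
        result.chosen_depth = best["depth"]
    return result


def _grid_sgd_fit(X, y, config: CascadeConfig, grid: dict, seed: int):
    base = make_base_learner(config, seed)
    n_splits = min(5, int(np.bincount(y).min()))
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        search = GridSearchCV(base, grid, scoring="f1_macro", cv=cv, n_jobs=1)
        search.fit(X, y)
        return search.best_estimator_
    base.fit(X, y)
    return base


def compare_methods(
    train: TabularDataset,
    test: TabularDataset,
    config: CascadeConfig,
    grid: dict | None = None,
    averaging: str = "macro",
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
    no_pca_depths: list[int] | None = None,
) -> ComparisonReport:
    """Compare four SGD-based methods on the same (cleaned, scaled,
    balanced) train/test pair:

    - ``plain_sgd``: grid-searched linear SGD on the raw features;
    - ``sgd_kg``: grid-searched SGD on the full quadratic expansion (no PCA);
    - ``cascade_no_pca``: the cascade with variance threshold 1 (full-rank,
      effectively no reduction), at its own depth-scan-selected depth;
    - ``cascade_pca``: the PCA-reduced cascade at the given config.
    """
    if grid is None:
        grid = DEFAULT_SGD_GRID
    report = ComparisonReport()
    d = train.n_features

    def record(name, y_tr_pred, y_te_pred, seconds, mean_width, n_levels, extra=None):
        entry = {
            "train": compute_metrics(train.labels, y_tr_pred, averaging),
            "test": compute_metrics(test.labels, y_te_pred, averaging),
            "fit_seconds": seconds,
            "mean_input_width": float(mean_width),
            "n_levels": n_levels,
        }
        if extra:
            entry.update(extra)
        report.methods[name] = entry

    # (a) plain linear SGD
    t0 = time.perf_counter()
    clf = _grid_sgd_fit(train.features, train.labels, config, grid, config.seed)
    record(
        "plain_sgd",
        clf.predict(train.features),
        clf.predict(test.features),
        time.perf_counter() - t0,
        d,
        1,
    )

    # (b) SGD on the full quadratic expansion
    spec = kg_expand_spec(d)
    if spec.output_dim > expansion_cap:
        raise ValueError(
            f"expansion too large: {spec.output_dim} columns exceeds cap {expansion_cap}"
        )
    t0 = time.perf_counter()
    Xe_tr = kg_expand(train.features, spec)
    clf = _grid_sgd_fit(Xe_tr, train.labels, config, grid, config.seed)
    seconds = time.perf_counter() - t0
    record(
        "sgd_kg",
        clf.predict(Xe_tr),
        clf.predict(kg_expand(test.features, spec)),
        seconds,
        spec.output_dim,
        1,
    )

    # (c) cascade without PCA reduction, at its own selected depth
    cfg_full = replace(config, variance_threshold=1.0, hyperparameter_grid=grid)
    scan = depth_scan(train, test, no_pca_depths or [1, 2, 3], cfg_full, averaging)
    depth_c = scan.chosen_depth or 1
    t0 = time.perf_counter()
    model_c = fit_cascade(train, replace(cfg_full, n_levels=depth_c))
    seconds = time.perf_counter() - t0
    widths_c = model_c.metadata["per_level_components"]
    record(
        "cascade_no_pca",
        predict_cascade(model_c, train.features),
        predict_cascade(model_c, test.features),
        seconds,
        np.mean(widths_c),
        depth_c,
        {"per_level_widths": widths_c, "selected_depth": depth_c},
    )

    # (d) the PCA-reduced cascade at the given config
    cfg_pca = replace(config, hyperparameter_grid=grid)
    t0 = time.perf_counter()
    model_d = fit_cascade(train, cfg_pca)
    seconds = time.perf_counter() - t0
    widths_d = model_d.metadata["per_level_components"]
    record(
        "cascade_pca",
        predict_cascade(model_d, train.features),
        predict_cascade(model_d, test.features),
        seconds,
        np.mean(widths_d),
        cfg_pca.n_levels,
        {"per_level_widths": widths_d},
    )
    return report
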