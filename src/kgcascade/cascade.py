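"""Training and application of the PCA-accelerated cascade of linear
classifiers.

Level i of an N-level cascade is trained on its own disjoint subset of the
training data, whose raw features are first augmented with the predictions
of levels 1..i-1 (one extra column per earlier level), then expanded with a
quadratic Kolmogorov-Gabor polynomial, reduced by PCA to the minimal
component set covering the variance threshold (default 95%), and fed to a
linear classifier fitted by stochastic gradient descent.  Because each
level squares the polynomial order implicitly, an N-level cascade realizes
a boundary of order 2^N while every classifier stays linear and fast; the
per-level PCA is what keeps the classifier input width small.

At application time the stored reducers are reused — never refitted — so
each level's classifier sees exactly the input space it was trained on.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .datasets import TabularDataset
from .features import (
    KGExpansionSpec,
    PCAReducer,
    apply_pca,
    fit_pca_reducer,
    kg_expand,
    kg_expand_spec,
)
from .preprocess import ScalerParams, partition_subsets

__all__ = [
    "CascadeConfig",
    "LevelModel",
    "CascadeModel",
    "CascadeFitError",
    "ModelFormatError",
    "make_base_learner",
    "level_seed",
    "fit_cascade",
    "augment_through_levels",
    "predict_cascade",
    "save_model",
    "load_model",
]

ARCHIVE_FORMAT = "kgc-1"

_SKLEARN_LOSS = {"logistic": "log_loss", "hinge": "hinge"}


class CascadeFitError(ValueError):
    """Raised when a level cannot be trained (subset too small/single class)."""


class ModelFormatError(ValueError):
    """Raised on corrupted or incompatible model archives."""


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of one cascade fit.

    ``augmentation_signal`` selects what each level appends for the next:
    the hard 0/1 label (default, the class marker) or the raw decision
    score.  ``hyperparameter_grid`` maps SGD parameter names to candidate
    lists; when set, each level's classifier is grid-searched by seeded
    5-fold cross-validated macro F1 on its own subset.
    """

    n_levels: int
    variance_threshold: float = 0.95
    loss: str = "logistic"
    alpha: float = 1e-4
    penalty: str = "l2"
    max_iter: int = 1000
    tol: float = 1e-3
    hyperparameter_grid: dict[str, list] | None = None
    augmentation_signal: str = "label"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError(
                f"variance_threshold must be in (0, 1], got {self.variance_threshold}"
            )
        if self.loss not in _SKLEARN_LOSS:
            raise ValueError(f"loss must be one of {sorted(_SKLEARN_LOSS)}, got {self.loss!r}")
        if self.penalty not in ("l2", "l1", "elasticnet"):
            raise ValueError(f"unsupported penalty {self.penalty!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.augmentation_signal not in ("label", "score"):
            raise ValueError(
                f"augmentation_signal must be 'label' or 'score', got {self.augmentation_signal!r}"
            )


@dataclass
class LevelModel:
    """One fitted cascade level: expansion spec, PCA reducer and the linear
    classifier it feeds (stored as weight vector + intercept)."""

    level_index: int
    raw_input_dim: int
    expansion: KGExpansionSpec
    reducer: PCAReducer
    coef: np.ndarray
    intercept: float
    loss: str
    train_f1: float = float("nan")

    def __post_init__(self) -> None:
        if self.expansion.input_dim != self.raw_input_dim:
            raise ValueError("expansion input width does not match level input width")
        if self.reducer.input_dim != self.expansion.output_dim:
            raise ValueError("reducer input width does not match expansion output width")
        if len(self.coef) != self.reducer.n_components:
            raise ValueError("classifier weight length does not match retained components")

    def decision(self, X_raw: np.ndarray) -> np.ndarray:
        """Decision score of this level on its raw (augmented) input."""
        Xr = apply_pca(kg_expand(X_raw, self.expansion), self.reducer)
        return Xr @ self.coef + self.intercept


@dataclass
class CascadeModel:
    """A trained cascade: optional scaler, ordered levels, config, metadata.

    ``training_record`` (in-memory only, not serialized) stores, per level,
    the subset row indices and the prediction features that were appended
    while fitting, so the application path can be audited against the
    training path.
    """

    original_dim: int
    scaler: ScalerParams | None
    levels: list[LevelModel]
    config: CascadeConfig
    metadata: dict = field(default_factory=dict)
    training_record: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for i, level in enumerate(self.levels, start=1):
            if level.level_index != i:
                raise ValueError("levels must be ordered by level_index starting at 1")
            if level.raw_input_dim != self.original_dim + i - 1:
                raise ValueError(
                    f"level {i} input width {level.raw_input_dim} != "
                    f"{self.original_dim} + {i - 1}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def level_seed(seed: int, level_index: int) -> int:
    """Per-level random seed derived from the cascade seed; level 1 uses the
    cascade seed itself."""
    return (seed + level_index - 1) % (2**31)


def make_base_learner(config: CascadeConfig, seed: int) -> SGDClassifier:
    """The cascade's base learner: a linear classifier fitted by SGD."""
    return SGDClassifier(
        loss=_SKLEARN_LOSS[config.loss],
        penalty=config.penalty,
        alpha=config.alpha,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=seed,
    )


def _fit_level_classifier(
    Xr: np.ndarray, y: np.ndarray, config: CascadeConfig, seed: int
) -> SGDClassifier:
    base = make_base_learner(config, seed)
    grid = config.hyperparameter_grid
    if grid:
        n_splits = min(5, int(np.bincount(y).min()))
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            search = GridSearchCV(base, grid, scoring="f1_macro", cv=cv, n_jobs=1)
            search.fit(Xr, y)
            return search.best_estimator_
    base.fit(Xr, y)
    return base


def _signal(decision: np.ndarray, kind: str) -> np.ndarray:
    return (decision > 0).astype(float) if kind == "label" else decision


def _augment(
    X_raw: np.ndarray, levels: list[LevelModel], signal: str, upto: int
) -> np.ndarray:
    cur = np.asarray(X_raw, dtype=float)
    for j in range(upto):
        level = levels[j]
        if cur.shape[1] != level.raw_input_dim:
            raise ValueError(
                f"level {level.level_index} expects width {level.raw_input_dim}, "
                f"got {cur.shape[1]}"
            )
        col = _signal(level.decision(cur), signal)
        cur = np.column_stack([cur, col])
    return cur


def fit_cascade(
    train: TabularDataset,
    config: CascadeConfig,
    scaler: ScalerParams | None = None,
) -> CascadeModel:
    """Train an N-level cascade on cleaned, scaled (and typically balanced)
    data.

    The training rows are partitioned into N equal disjoint subsets with
    the config seed.  Level i is fitted on subset i after augmenting it
    through levels 1..i-1 (reusing their stored reducers), expanding with
    the quadratic polynomial, and reducing with a freshly fitted PCA at the
    variance threshold.  Deterministic for a fixed config.
    """
    X, y = train.features, train.labels
    if np.isnan(X).any():
        raise ValueError("missing cells present: run clean() before fitting")
    if config.n_levels > train.n_rows:
        raise CascadeFitError(
            f"n_levels={config.n_levels} exceeds row count {train.n_rows}"
        )
    d = train.n_features
    plan = partition_subsets(train, config.n_levels, config.seed)

    levels: list[LevelModel] = []
    record: list[dict] = []
    for i, idx in enumerate(plan.subsets, start=1):
        Xs, ys = X[idx], y[idx]
        if len(idx) < 2:
            raise CascadeFitError(f"subset for level {i} has fewer than 2 rows")
        if len(np.unique(ys)) < 2:
            raise CascadeFitError(
                f"subset for level {i} contains a single class; "
                "use fewer levels or rebalance"
            )
        Xaug = _augment(Xs, levels, config.augmentation_signal, i - 1)
        spec = kg_expand_spec(Xaug.shape[1])
        Xe = kg_expand(Xaug, spec)
        reducer = fit_pca_reducer(Xe, config.variance_threshold)
        Xr = apply_pca(Xe, reducer)
        lseed = level_seed(config.seed, i)
        clf = _fit_level_classifier(Xr, ys, config, lseed)
        coef = np.asarray(clf.coef_).ravel()
        intercept = float(np.asarray(clf.intercept_).ravel()[0])
        train_f1 = float(f1_score(ys, clf.predict(Xr), average="macro"))
        levels.append(
            LevelModel(i, Xaug.shape[1], spec, reducer, coef, intercept, config.loss, train_f1)
        )
        record.append({"level": i, "indices": idx, "appended": Xaug[:, d:].copy()})

    model = CascadeModel(
        original_dim=d,
        scaler=scaler,
        levels=levels,
        config=config,
        metadata={
            "n_levels": config.n_levels,
            "variance_threshold": config.variance_threshold,
            "per_level_components": [lv.reducer.n_components for lv in levels],
            "per_level_train_f1": [lv.train_f1 for lv in levels],
            "feature_names": list(train.feature_names),
        },
    )
    model.training_record = record
    return model


def augment_through_levels(
    X_raw: np.ndarray, model: CascadeModel, upto_level: int
) -> np.ndarray:
    """Raw matrix plus one appended prediction column per level 1..upto_level.

    This is the application-mode propagation: each level expands the
    current matrix, projects with its stored reducer, predicts, and the
    prediction (label or score per config) becomes a new feature.
    """
    if not 0 <= upto_level <= model.n_levels:
        raise ValueError(
            f"upto_level must be in [0, {model.n_levels}], got {upto_level}"
        )
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim != 2 or X_raw.shape[1] != model.original_dim:
        raise ValueError(
            f"input has shape {X_raw.shape}, expected (n, {model.original_dim})"
        )
    return _augment(X_raw, model.levels, model.config.augmentation_signal, upto_level)


def predict_cascade(
    model: CascadeModel, X_raw: np.ndarray, auto_scale: bool = False
) -> np.ndarray:
    """Class labels from the last cascade level.

    ``X_raw`` must already be scaled like the training data unless
    ``auto_scale`` is set and the model carries its scaler.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim != 2 or X_raw.shape[1] != model.original_dim:
        raise ValueError(
            f"input has shape {X_raw.shape}, expected (n, {model.original_dim})"
        )
    if auto_scale:
        if model.scaler is None:
            raise ValueError("auto_scale requested but model carries no scaler")
        s = model.scaler
        safe = np.where(s.scale > 0, s.scale, 1.0)
        X_raw = (X_raw - s.location) / safe
        X_raw[:, s.scale == 0] = 0.0
    cur = _augment(X_raw, model.levels, model.config.augmentation_signal, model.n_levels - 1)
    return (model.levels[-1].decision(cur) > 0).astype(int)


# ---------------------------------------------------------------------------
# Persistence: a versioned zip container of raw array blobs + JSON metadata.
# Zip entry timestamps are pinned so identical models serialize to identical
# bytes.

_EPOCH = (1980, 1, 1, 0, 0, 0)


def _write_array(zf: zipfile.ZipFile, name: str, arr: np.ndarray) -> None:
    buf = io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr), allow_pickle=False)
    info = zipfile.ZipInfo(name, date_time=_EPOCH)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, buf.getvalue())


def _read_array(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    with zf.open(name) as fh:
        return np.lib.format.read_array(io.BytesIO(fh.read()), allow_pickle=False)


def save_model(model: CascadeModel, path) -> None:
    """Write the model as a ``kgc-1`` archive (arrays + JSON metadata)."""
    meta: dict[str, Any] = {
        "format": ARCHIVE_FORMAT,
        "original_dim": model.original_dim,
        "config": asdict(model.config),
        "scaler": None if model.scaler is None else {"kind": model.scaler.kind},
        "n_levels": model.n_levels,
        "variance_threshold": model.config.variance_threshold,
        "per_level_components": [lv.reducer.n_components for lv in model.levels],
        "levels": [
            {
                "level_index": lv.level_index,
                "raw_input_dim": lv.raw_input_dim,
                "n_components": lv.reducer.n_components,
                "loss": lv.loss,
                "train_f1": lv.train_f1,
            }
            for lv in model.levels
        ],
        "feature_names": model.metadata.get("feature_names"),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("meta.json", date_time=_EPOCH)
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, json.dumps(meta, sort_keys=True, indent=1))
        if model.scaler is not None:
            _write_array(zf, "scaler_location.npy", model.scaler.location)
            _write_array(zf, "scaler_scale.npy", model.scaler.scale)
        for lv in model.levels:
            p = f"level{lv.level_index}"
            _write_array(zf, f"{p}_center.npy", lv.reducer.center)
            _write_array(zf, f"{p}_components.npy", lv.reducer.components)
            _write_array(zf, f"{p}_ratios.npy", lv.reducer.explained_variance_ratios)
            _write_array(zf, f"{p}_coef.npy", lv.coef)
            _write_array(zf, f"{p}_intercept.npy", np.array([lv.intercept]))


def load_model(path) -> CascadeModel:
    """Read a ``kgc-1`` archive; predictions of the loaded model are
    bit-identical to the saved one."""
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != ARCHIVE_FORMAT:
                raise ModelFormatError(
                    f"unsupported archive format {meta.get('format')!r}, "
                    f"expected {ARCHIVE_FORMAT!r}"
                )
            config = CascadeConfig(**meta["config"])
            scaler = None
            if meta["scaler"] is not None:
                scaler = ScalerParams(
                    meta["scaler"]["kind"],
                    _read_array(zf, "scaler_location.npy"),
                    _read_array(zf, "scaler_scale.npy"),
                )
            levels = []
            for entry in meta["levels"]:
                i = entry["level_index"]
                p = f"level{i}"
                spec = kg_expand_spec(entry["raw_input_dim"])
                reducer = PCAReducer(
                    input_dim=spec.output_dim,
                    center=_read_array(zf, f"{p}_center.npy"),
                    components=_read_array(zf, f"{p}_components.npy"),
                    explained_variance_ratios=_read_array(zf, f"{p}_ratios.npy"),
                    variance_threshold=config.variance_threshold,
                )
                levels.append(
                    LevelModel(
                        i,
                        entry["raw_input_dim"],
                        spec,
                        reducer,
                        _read_array(zf, f"{p}_coef.npy"),
                        float(_read_array(zf, f"{p}_intercept.npy")[0]),
                        entry["loss"],
                        entry.get("train_f1", float("nan")),
                    )
                )
            model = CascadeModel(
                original_dim=meta["original_dim"],
                scaler=scaler,
                levels=levels,
                config=config,
                metadata={
                    "n_levels": meta["n_levels"],
                    "variance_threshold": meta["variance_threshold"],
                    "per_level_components": meta["per_level_components"],
                    "feature_names": meta.get("feature_names"),
                },
            )
            return model
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, EOFError, OSError) as exc:
        raise ModelFormatError(f"cannot load model archive {path}: {exc}") from exc
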