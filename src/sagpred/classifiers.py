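"""SVM and gradient-boosted-tree classifiers with exhaustive grid search.

The training pipeline is: per-column standardization (SVM family only —
RBF kernels are scale-sensitive, tree splits are not) -> optional PCA to a
chosen dimension -> classifier refit on all rows with the grid-search-best
hyperparameters. The fitted state is persisted as a self-contained
:class:`ModelBundle` that reproduces scores bitwise after reload.

Grid search is a native exhaustive loop over the declared axes so that ties
are broken by the earlier lexicographic position in the declared grid order,
with identical stratified folds reused for every grid point.

SVM positive-class scores come from Platt-style sigmoid calibration fit on
cross-validated decision values (``SVC(probability=True)``); boosted trees
report their native probability.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import __version__ as _toolkit_version
from .dim_reduction import PCATransform, apply_pca, fit_pca
from .encodings import EncodingSpec, FeatureMatrix, dimensionality

logger = logging.getLogger("sagpred.classifiers")

SVM = "svm"
GBT = "gbt"

#: Default hyperparameter grids. The axis names are fixed by the method
#: (cost/gamma/kernel for SVM; the six boosted-tree knobs); the values are
#: this toolkit's documented defaults and fully overridable.
DEFAULT_SVM_GRID: dict[str, tuple] = {
    "cost": (0.1, 1.0, 10.0, 100.0),
    "gamma": (1e-4, 1e-3, 1e-2, 1e-1, "scale"),
    "kernel": ("linear", "rbf"),
}
DEFAULT_GBT_GRID: dict[str, tuple] = {
    "max_depth": (3, 6, 9),
    "subsample": (0.7, 1.0),
    "min_child_weight": (1, 5),
    "colsample_bytree": (0.7, 1.0),
    "gamma": (0, 1),
    "learning_rate": (0.05, 0.1, 0.3),
}

DEFAULT_SVM_PARAMS = {"cost": 1.0, "gamma": "scale", "kernel": "rbf"}
DEFAULT_GBT_PARAMS = {
    "max_depth": 6,
    "subsample": 1.0,
    "min_child_weight": 1,
    "colsample_bytree": 1.0,
    "gamma": 0,
    "learning_rate": 0.1,
}


class ClassifierError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Classifier family, hyperparameter grid and cross-validation protocol."""

    family: str = SVM
    svm_grid: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_SVM_GRID))
    gbt_grid: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_GBT_GRID))
    cv_folds: int = 5
    scoring: str = "f1"
    seed: int = 17
    balanced: bool = False
    #: When set, grid search is skipped and these hyperparameters are used.
    fixed_params: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.family not in (SVM, GBT):
            raise ValueError(f"family must be '{SVM}' or '{GBT}', got {self.family!r}")
        grid = self.grid
        if any(len(axis) == 0 for axis in grid.values()):
            raise ValueError("every grid axis must be non-empty")

    @property
    def grid(self) -> dict[str, tuple]:
        return self.svm_grid if self.family == SVM else self.gbt_grid

    def grid_points(self) -> list[dict[str, Any]]:
        """Exhaustive grid, ordered lexicographically over the declared axes."""
        keys = list(self.grid.keys())
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]

    def default_params(self) -> dict[str, Any]:
        return dict(DEFAULT_SVM_PARAMS if self.family == SVM else DEFAULT_GBT_PARAMS)


def build_estimator(
    family: str, params: dict[str, Any], seed: int = 17, balanced: bool = False
):
    """Instantiate an unfitted classifier for one hyperparameter point."""
    if family == SVM:
        base = SVC(
            C=params["cost"],
            kernel=params["kernel"],
            gamma=params.get("gamma", "scale"),
            class_weight="balanced" if balanced else None,
            tol=1e-7,  # tight stop: decision values stable under rotations
        )
        # Platt-style sigmoid calibration fit on cross-validated decision
        # values; ensemble=False refits the SVC on all training rows.
        return CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
    if family == GBT:
        return XGBClassifier(
            n_estimators=100,
            max_depth=params["max_depth"],
            subsample=params["subsample"],
            min_child_weight=params["min_child_weight"],
            colsample_bytree=params["colsample_bytree"],
            gamma=params["gamma"],
            learning_rate=params["learning_rate"],
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise ClassifierError(f"unknown family {family!r}")


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs; zero-variance columns get scale 1 with a warning."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = scale == 0
    if zero.any():
        logger.warning(
            "%d zero-variance feature column(s); their scale is set to 1",
            int(zero.sum()),
        )
        scale = scale.copy()
        scale[zero] = 1.0
    return mean, scale


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    Xa = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    ya = np.asarray(y)
    if Xa.shape[0] != ya.shape[0]:
        raise ClassifierError(
            f"feature rows ({Xa.shape[0]}) and labels ({ya.shape[0]}) do not align"
        )
    if not np.isfinite(Xa).all():
        raise ClassifierError("non-finite feature values")
    if np.unique(ya).size < 2:
        raise ClassifierError("both classes must be present in the labels")
    return Xa, ya


@dataclass
class FoldPipeline:
    """One fitted (scaler -> optional PCA -> classifier) pipeline."""

    family: str
    scaler_mean: np.ndarray | None
    scaler_scale: np.ndarray | None
    pca: PCATransform | None
    n_components: int | None
    clf: Any
    threshold: float = 0.5

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=np.float64)
        if self.scaler_mean is not None:
            Z = (Z - self.scaler_mean) / self.scaler_scale
        if self.pca is not None:
            Z = apply_pca(self.pca, Z, self.n_components).values
        return Z

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(self.transform(X))[:, 1]

    def labels(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= self.threshold).astype(int)


def fit_fold_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    params: dict[str, Any] | None = None,
    pca_dims: int | None = None,
) -> FoldPipeline:
    """Fit the full pipeline on one set of training rows only.

    Training rows are put into a canonical order first (labels, then feature
    values), so the fitted pipeline — including the calibration folds — is
    invariant to the order rows arrive in.
    """
    params = params or config.fixed_params or config.default_params()
    order = np.lexsort(np.vstack([X.T, y[np.newaxis, :].astype(np.float64)]))
    X = X[order]
    y = np.asarray(y)[order]
    if config.family == SVM:
        mean, scale = _fit_scaler(X)
        Z = (X - mean) / scale
    else:
        mean = scale = None
        Z = X
    pca = None
    if pca_dims is not None:
        pca = fit_pca(Z)
        Z = apply_pca(pca, Z, pca_dims).values
    clf = build_estimator(config.family, params, seed=config.seed, balanced=config.balanced)
    clf.fit(Z, y)
    return FoldPipeline(
        family=config.family,
        scaler_mean=mean,
        scaler_scale=scale,
        pca=pca,
        n_components=pca_dims,
        clf=clf,
    )


def score_fold(pipeline: FoldPipeline, X: np.ndarray, y: np.ndarray) -> float:
    """Held-out F1 of a fitted fold pipeline."""
    return float(f1_score(y, pipeline.labels(X), zero_division=0))


def grid_search(
    X, y, config: ModelConfig, pca_dims: int | None = None
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Exhaustive stratified-CV grid search scored by fold-mean F1.

    Deterministic given the config seed; ties are broken by the earlier
    position in the declared grid order. Returns the winning parameters and
    the full score table (one row per grid point).
    """
    Xa, ya = _as_xy(X, y)
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    splits = list(skf.split(Xa, ya))
    rows = []
    best_params: dict[str, Any] | None = None
    best_score = -np.inf
    for point in config.grid_points():
        fold_scores = [
            score_fold(
                fit_fold_pipeline(Xa[tr], ya[tr], config, params=point, pca_dims=pca_dims),
                Xa[te],
                ya[te],
            )
            for tr, te in splits
        ]
        mean_score = float(np.mean(fold_scores))
        rows.append({**point, "mean_f1": mean_score, "fold_f1": fold_scores})
        if mean_score > best_score:  # strict: first best wins on ties
            best_score = mean_score
            best_params = dict(point)
    return best_params, pd.DataFrame(rows)


@dataclass
class ModelBundle:
    """A persisted, self-contained prediction pipeline.

    Captures the encoding spec, the training-row scaling parameters, the
    optional PCA transform, the chosen classifier and its decision
    threshold, plus training metadata. Saving then loading a bundle
    reproduces scores bitwise on a fixed input matrix.
    """

    spec: EncodingSpec | None
    pipeline: FoldPipeline
    family: str
    params: dict[str, Any]
    decision_threshold: float = 0.5
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def expected_n_features(self) -> int:
        if self.pipeline.scaler_mean is not None:
            return int(self.pipeline.scaler_mean.size)
        if self.pipeline.pca is not None:
            return int(self.pipeline.pca.n_features)
        return int(self.metadata["n_features"])

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise ClassifierError(f"{path} does not contain a model bundle")
        return bundle


def train(
    X, y, config: ModelConfig, pca_dims: int | None = None
) -> ModelBundle:
    """Grid-search hyperparameters and refit the pipeline on all rows.

    With ``config.fixed_params`` set the search is skipped. The returned
    bundle carries everything prediction needs.
    """
    Xa, ya = _as_xy(X, y)
    if config.fixed_params is not None:
        best_params = dict(config.fixed_params)
    else:
        best_params, _ = grid_search(Xa, ya, config, pca_dims=pca_dims)
    pipeline = fit_fold_pipeline(Xa, ya, config, params=best_params, pca_dims=pca_dims)
    spec = X.spec if isinstance(X, FeatureMatrix) else None
    metadata = {
        "n_pos": int((ya == 1).sum()),
        "n_neg": int((ya == 0).sum()),
        "seed": config.seed,
        "n_features": int(Xa.shape[1]),
        "pca_dims": pca_dims,
        "toolkit_version": _toolkit_version,
    }
    return ModelBundle(
        spec=spec,
        pipeline=pipeline,
        family=config.family,
        params=best_params,
        decision_threshold=0.5,
        metadata=metadata,
    )


def predict_scores(bundle: ModelBundle, X) -> np.ndarray:
    """Positive-class probability per row, in [0, 1]."""
    Xa = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    expected = bundle.expected_n_features
    if bundle.spec is not None:
        expected = dimensionality(bundle.spec)
    if Xa.shape[1] != expected:
        raise ClassifierError(
            f"feature width mismatch: bundle expects {expected} columns, "
            f"input has {Xa.shape[1]}"
        )
    return bundle.pipeline.scores(Xa)


def predict_labels(bundle: ModelBundle, X) -> np.ndarray:
    """Hard 0/1 labels at the bundle's decision threshold."""
    return (predict_scores(bundle, X) >= bundle.decision_threshold).astype(int)
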