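"""PCA projection of fused feature matrices and the discriminative-dimension scan.

PCA is always re-fit inside every cross-validation training fold, never on
held-out rows: fitting it once on the full data before splitting would leak
information and can select a different "best" dimension. Component signs are
fixed so each loading vector's largest-magnitude coordinate is positive,
making serialized transforms reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .encodings import FeatureMatrix


class DimReductionError(ValueError):
    pass


@dataclass
class PCATransform:
    """A fitted centering + orthonormal projection."""

    mean_vector: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray
    feature_names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_features(self) -> int:
        return self.components.shape[1]


def _as_array(matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=np.float64)


def _check_finite(X: np.ndarray, col_names: list[str] | None) -> None:
    bad = np.flatnonzero(~np.isfinite(X).all(axis=0))
    if bad.size:
        names = [col_names[i] for i in bad[:10]] if col_names else bad[:10].tolist()
        raise DimReductionError(f"non-finite values in columns: {names}")


def fit_pca(matrix: FeatureMatrix | np.ndarray) -> PCATransform:
    """Fit PCA (centering + full eigen-decomposition of the covariance).

    Deterministic: the full SVD solver is used and each component's sign is
    fixed so its largest-magnitude coordinate is positive.
    """
    X = _as_array(matrix)
    names = matrix.col_names if isinstance(matrix, FeatureMatrix) else None
    if X.shape[0] < 2:
        raise DimReductionError("PCA needs at least 2 rows")
    _check_finite(X, names)
    p = PCA(svd_solver="full")
    p.fit(X)
    components = p.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCATransform(
        mean_vector=p.mean_.copy(),
        components=components,
        explained_variance=p.explained_variance_.copy(),
        feature_names=list(names) if names is not None else None,
    )


def apply_pca(
    transform: PCATransform, matrix: FeatureMatrix | np.ndarray, n: int
) -> FeatureMatrix:
    """Project onto the first ``n`` components; rows are preserved.

    Projecting with ``n`` components then truncating to ``m < n`` columns
    equals projecting with ``m`` directly.
    """
    X = _as_array(matrix)
    if not 1 <= n <= transform.n_components:
        raise DimReductionError(
            f"n must be in [1, {transform.n_components}], got {n}"
        )
    if X.shape[1] != transform.n_features:
        raise DimReductionError(
            f"column mismatch: transform fitted on {transform.n_features} "
            f"features, input has {X.shape[1]}"
        )
    if isinstance(matrix, FeatureMatrix) and transform.feature_names is not None:
        if matrix.col_names != transform.feature_names:
            raise DimReductionError("input column names differ from fitting columns")
    projected = (X - transform.mean_vector) @ transform.components[:n].T
    row_ids = (
        matrix.row_ids
        if isinstance(matrix, FeatureMatrix)
        else [str(i) for i in range(X.shape[0])]
    )
    return FeatureMatrix(
        row_ids=list(row_ids),
        col_names=[f"pc{i + 1}" for i in range(n)],
        values=projected,
    )


def inverse_pca(transform: PCATransform, projected: np.ndarray) -> np.ndarray:
    """Map projected coordinates back to the original feature space."""
    n = projected.shape[1]
    return projected @ transform.components[:n] + transform.mean_vector


@dataclass
class DimensionScanResult:
    """Cross-validated F1 per candidate retained-dimension count."""

    candidate_dims: list[int]
    score_per_dim: list[float]
    best_dim: int
    best_score: float


def default_candidate_dims(full_width: int) -> list[int]:
    """Percent-of-width candidate grid: 1/2/5/10/25/50/75/90/100 %, deduplicated."""
    fracs = (0.01, 0.02, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 1.00)
    dims = sorted({max(1, round(full_width * f)) for f in fracs})
    return dims


def scan_dimensions(
    train: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    candidate_dims: list[int],
    model_config,
    cv_folds: int = 5,
    seed: int = 17,
) -> DimensionScanResult:
    """Pick the most discriminative number of retained PCA dimensions.

    For each candidate, PCA (and any feature scaling the classifier family
    needs) is re-fit on every training fold only; fold-averaged F1 is
    recorded and the argmax returned, ties resolved to the smallest
    dimension.
    """
    from .classifiers import fit_fold_pipeline, score_fold  # local: avoid cycle

    X = _as_array(train)
    y = np.asarray(labels)
    if not candidate_dims:
        raise DimReductionError("candidate_dims must be non-empty")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    max_rank = min(min(len(tr) for tr, _ in splits), X.shape[1])
    too_big = [d for d in candidate_dims if d > max_rank]
    if too_big:
        raise DimReductionError(
            f"candidate dims {too_big} exceed the available rank {max_rank}"
        )
    scores: list[float] = []
    for n_dim in candidate_dims:
        fold_scores = []
        for tr, te in splits:
            pipeline = fit_fold_pipeline(
                X[tr], y[tr], model_config, pca_dims=n_dim
            )
            fold_scores.append(score_fold(pipeline, X[te], y[te]))
        scores.append(float(np.mean(fold_scores)))
    order = sorted(range(len(candidate_dims)), key=lambda i: candidate_dims[i])
    best_i = max(order, key=lambda i: (scores[i], -candidate_dims[i]))
    return DimensionScanResult(
        candidate_dims=list(candidate_dims),
        score_per_dim=scores,
        best_dim=candidate_dims[best_i],
        best_score=scores[best_i],
    )
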