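"""Binary RBF-kernel SVM with decade-grid hyperparameter search.

Features are z-score standardized with statistics fitted on the training
rows (zero-variance features are dropped and recorded); the SVM itself is
scikit-learn's libsvm binding. Predictions are defined as the sign of the
decision function so that ``predict`` and ``decision_scores`` can never
disagree.

Two tuning criteria are available: ``"paper"`` scores each (gamma, cost)
pair by balanced accuracy on the full training data (fast, but optimistic),
while the default ``"cv"`` scores by mean balanced accuracy over 5-fold
stratified cross-validation. Ties prefer smaller cost, then smaller gamma.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ModelIOError, SchemaError

__all__ = [
    "SVMConfig",
    "TrainedClassifier",
    "tune_hyperparameters",
    "train",
    "predict",
    "decision_scores",
    "save_model",
    "load_model",
]

_MODEL_FORMAT = "songscan-model-v1"

# bound libsvm's iteration count so pathological grid corners cannot hang
_MAX_ITER = 200_000


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters and grid-search settings."""

    gamma: float = 1.0
    cost: float = 1.0
    grid_exponents: tuple[int, ...] = tuple(range(-10, 11))
    class_weighting: str = "balanced"
    tuning_mode: str = "cv"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError(f"gamma and cost must be > 0, got ({self.gamma}, {self.cost})")
        if not self.grid_exponents:
            raise ValueError("grid_exponents must be non-empty")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError(f"class_weighting must be none|balanced, got {self.class_weighting}")
        if self.tuning_mode not in ("paper", "cv"):
            raise ValueError(f"tuning_mode must be paper|cv, got {self.tuning_mode}")

    def grid_pairs(self) -> list[tuple[float, float]]:
        """All (gamma, cost) pairs of the decade grid."""
        values = [10.0**k for k in self.grid_exponents]
        return [(g, c) for g in values for c in values]


@dataclass
class TrainedClassifier:
    """Fitted SVM state plus the feature schema and standardization it expects."""

    svm: SVC
    schema: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    dropped_features: tuple[str, ...]
    config: SVMConfig
    format_version: str = _MODEL_FORMAT


def _as_matrix(features, schema: tuple[str, ...] | None = None):
    """Coerce features to (matrix, schema); DataFrames are schema-keyed."""
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c not in ("source_id", "selection_id")]
        if schema is not None:
            missing = [c for c in schema if c not in cols]
            extra = [c for c in cols if c not in schema]
            if missing or extra:
                raise SchemaError(
                    f"feature schema mismatch: missing {missing}, unexpected {extra}"
                )
            cols = list(schema)
        return features[cols].to_numpy(dtype=np.float64), tuple(cols)
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    names = tuple(f"f{i}" for i in range(x.shape[1]))
    if schema is not None:
        if len(schema) != x.shape[1]:
            raise SchemaError(
                f"feature schema mismatch: model expects {len(schema)} features, got {x.shape[1]}"
            )
        names = schema
    return x, names


def _check_binary(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; need both presence and absence")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")


def _fit_svm(x: np.ndarray, y: np.ndarray, gamma: float, cost: float, weighting: str) -> SVC:
    svm = SVC(
        kernel="rbf",
        gamma=gamma,
        C=cost,
        class_weight="balanced" if weighting == "balanced" else None,
        max_iter=_MAX_ITER,
        cache_size=200,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svm.fit(x, y)
    return svm


def _standardize_fit(x: np.ndarray):
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    return mean, sd, keep


def _bac(pred: np.ndarray, truth: np.ndarray) -> float:
    p_a = (pred[truth == 1] == 1).mean()
    p_b = (pred[truth == 0] == 0).mean()
    return (p_a + p_b) / 2.0 * 100.0


def tune_hyperparameters(features, labels, cfg: SVMConfig | None = None, seed: int = 0) -> SVMConfig:
    """Grid-search (gamma, cost) and return the config with them filled in."""
    cfg = cfg or SVMConfig()
    x, _ = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    _check_binary(y)
    if cfg.tuning_mode == "cv":
        n_splits = min(5, int(np.bincount(y).min()))
        folds = list(
            StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed).split(x, y)
        )
    best_key, best_pair = None, None
    for gamma, cost in cfg.grid_pairs():
        if cfg.tuning_mode == "paper":
            mean, sd, keep = _standardize_fit(x)
            xs = (x[:, keep] - mean[keep]) / sd[keep]
            svm = _fit_svm(xs, y, gamma, cost, cfg.class_weighting)
            score = _bac(np.asarray(svm.decision_function(xs) > 0, dtype=int), y)
        else:
            scores = []
            for train_idx, test_idx in folds:
                mean, sd, keep = _standardize_fit(x[train_idx])
                xs_tr = (x[train_idx][:, keep] - mean[keep]) / sd[keep]
                xs_te = (x[test_idx][:, keep] - mean[keep]) / sd[keep]
                svm = _fit_svm(xs_tr, y[train_idx], gamma, cost, cfg.class_weighting)
                scores.append(
                    _bac(np.asarray(svm.decision_function(xs_te) > 0, dtype=int), y[test_idx])
                )
            score = float(np.mean(scores))
        key = (-score, cost, gamma)
        if best_key is None or key < best_key:
            best_key, best_pair = key, (gamma, cost)
    return replace(cfg, gamma=best_pair[0], cost=best_pair[1])


def train(features, labels, cfg: SVMConfig | None = None) -> TrainedClassifier:
    """Fit standardization + RBF-SVM on a feature table and binary labels."""
    cfg = cfg or SVMConfig()
    x, schema = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(y) != x.shape[0]:
        raise ValueError("features and labels have different lengths")
    bad = ~np.isfinite(x).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite features in row(s) {np.flatnonzero(bad).tolist()}")
    _check_binary(y)
    mean, sd, keep = _standardize_fit(x)
    if not keep.any():
        raise ValueError("all features have zero variance")
    dropped = tuple(name for name, k in zip(schema, keep) if not k)
    schema_kept = tuple(name for name, k in zip(schema, keep) if k)
    xs = (x[:, keep] - mean[keep]) / sd[keep]
    svm = _fit_svm(xs, y, cfg.gamma, cfg.cost, cfg.class_weighting)
    return TrainedClassifier(
        svm=svm,
        schema=schema_kept,
        mean=mean[keep],
        sd=sd[keep],
        dropped_features=dropped,
        config=cfg,
    )


def _prepare(model: TrainedClassifier, features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c not in ("source_id", "selection_id")]
        missing = [c for c in model.schema if c not in cols]
        extra = [c for c in cols if c not in model.schema and c not in model.dropped_features]
        if missing or extra:
            raise SchemaError(f"feature schema mismatch: missing {missing}, unexpected {extra}")
        x = features[list(model.schema)].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(features, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != len(model.schema):
            raise SchemaError(
                f"feature schema mismatch: model expects {len(model.schema)} columns"
            )
    return (x - model.mean) / model.sd


def decision_scores(model: TrainedClassifier, features) -> np.ndarray:
    """Signed distances to the decision boundary (positive = presence)."""
    return np.asarray(model.svm.decision_function(_prepare(model, features)))


def predict(model: TrainedClassifier, features) -> np.ndarray:
    """Binary labels: 1 (presence) where the decision score is > 0."""
    return (decision_scores(model, features) > 0).astype(int)


def save_model(model: TrainedClassifier, path) -> None:
    """Serialize a trained classifier (pickle with a format tag)."""
    payload = {"format": _MODEL_FORMAT, "model": model}
    with open(path, "wb") as handle:
        pickle.dump(payload, handle, protocol=4)


def load_model(path) -> TrainedClassifier:
    """Load a model saved by :func:`save_model`; errors on bad/old files."""
    try:
        with open(path, "rb") as handle:
            payload = pickle.load(handle)
    except (pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise ModelIOError(f"cannot load model from {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelIOError(
            f"{path!r} is not a {_MODEL_FORMAT} file (got {payload.get('format') if isinstance(payload, dict) else type(payload)})"
        )
    return payload["model"]
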