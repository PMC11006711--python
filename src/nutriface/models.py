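"""Classifiers and cross-validation for the three-class nutrition problem.

The primary classifier is a back-propagation (BP) network: one hidden
layer of logistic units trained by stochastic gradient descent with a
softmax/cross-entropy output, 50 epochs by default.  Five classic
baselines (AdaBoost, ExtraTrees, random forest, XGBoost, KNN) share the
same prediction contract: a 3-vector of class probabilities per subject,
padded with zeros for classes absent from the training fold.

Cross-validation is stratified 5-fold; PCA (and any feature weighting)
is fitted on the training portion of each fold only, so no information
leaks from validation subjects into the fitted transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .evaluation import MetricSet, evaluate_predictions
from .features import PCAModel, pca_fit, pca_transform

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "Prediction",
    "ModelError",
    "MODEL_KINDS",
    "train_bp",
    "train_baseline",
    "train_model",
    "cross_validate",
    "CrossValResult",
]

N_CLASSES = 3

MODEL_KINDS = ("bp", "adaboost", "extratree", "rf", "xgboost", "knn")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    model_kind: str = "bp"
    hidden_units: int = 64
    activation: str = "logistic"
    learning_rate: float = 0.01
    rounds: int = 50
    batch: int = 32
    seed: int = 0
    n_folds: int = 5
    knn_k: int = 5

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ModelError(f"unknown model kind {self.model_kind!r}")
        if self.rounds < 1 or self.n_folds < 2 or self.learning_rate <= 0:
            raise ModelError("invalid training configuration")


@dataclass
class Prediction:
    probabilities: np.ndarray  # (n, 3)

    @property
    def hard_class(self) -> np.ndarray:
        # argmax with ties broken toward the lower class index
        return self.probabilities.argmax(axis=1)


@dataclass
class TrainedModel:
    model_kind: str
    estimator: object
    classes_seen: np.ndarray
    pca: PCAModel | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities as an (n, 3) matrix summing to 1 per row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.pca is not None:
            X = pca_transform(self.pca, X)
        raw = self.estimator.predict_proba(X)
        out = np.zeros((X.shape[0], N_CLASSES))
        for j, cls in enumerate(self.classes_seen):
            out[:, int(cls)] = raw[:, j]
        # numerical renormalization (classes absent from training keep 0)
        out /= out.sum(axis=1, keepdims=True)
        return out

    def predict(self, X: np.ndarray) -> Prediction:
        return Prediction(self.predict_proba(X))


def _build_estimator(config: TrainConfig):
    kind, seed = config.model_kind, config.seed
    if kind == "bp":
        return MLPClassifier(
            hidden_layer_sizes=(config.hidden_units,),
            activation=config.activation,
            solver="sgd",
            learning_rate_init=config.learning_rate,
            max_iter=config.rounds,
            batch_size=config.batch,
            momentum=0.9,
            n_iter_no_change=config.rounds,  # always run the full round budget
            random_state=seed,
        )
    if kind == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if kind == "extratree":
        return ExtraTreesClassifier(random_state=seed)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, eval_metric="mlogloss")
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_k)
    raise ModelError(f"unknown model kind {kind!r}")


def train_model(features: np.ndarray, labels, config: TrainConfig) -> TrainedModel:
    """Fit the configured classifier; deterministic given (data, config, seed)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ModelError("features must be (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ModelError("features must be finite")
    classes = np.unique(y)
    if classes.size < 2:
        raise ModelError("training requires at least two classes")
    est = _build_estimator(config)
    if config.model_kind == "xgboost":
        # xgboost wants contiguous 0..k-1 labels
        remap = {c: i for i, c in enumerate(classes)}
        y_fit = np.array([remap[c] for c in y])
    else:
        y_fit = y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y_fit)
    return TrainedModel(model_kind=config.model_kind, estimator=est,
                        classes_seen=classes)


def train_bp(features, labels, config: TrainConfig | None = None) -> TrainedModel:
    config = replace(config or TrainConfig(), model_kind="bp")
    return train_model(features, labels, config)


def train_baseline(features, labels, config: TrainConfig) -> TrainedModel:
    if config.model_kind == "bp":
        raise ModelError("train_baseline expects a non-BP model kind")
    return train_model(features, labels, config)


@dataclass
class CrossValResult:
    fold_metrics: list[MetricSet]
    pooled: MetricSet
    fold_indices: list[np.ndarray]
    pooled_probabilities: np.ndarray  # (n, 3), rows in original order
    labels: np.ndarray

    @property
    def micro_auc(self) -> float:
        return self.pooled.auc


def cross_validate(
    features: np.ndarray,
    labels,
    config: TrainConfig | None = None,
    pca_variance: float | None = 0.95,
    pca_components: int | None = None,
    bootstrap_B: int = 200,
) -> CrossValResult:
    """Stratified k-fold CV with per-fold PCA (no leakage).

    PCA is fitted on each fold's training subjects only and applied to the
    held-out subjects; returned probabilities are the out-of-fold
    predictions assembled in the original sample order.
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.shape[0] < config.n_folds:
        raise ModelError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    pooled_probs = np.zeros((X.shape[0], N_CLASSES))
    fold_metrics: list[MetricSet] = []
    fold_indices: list[np.ndarray] = []
    for k, (tr, va) in enumerate(skf.split(X, y)):
        if np.unique(y[va]).size < 2 or np.unique(y[tr]).size < 2:
            raise ModelError("a fold lacks class diversity; reduce n_folds")
        Xtr, Xva = X[tr], X[va]
        pca = None
        if pca_variance is not None or pca_components is not None:
            pca = pca_fit(Xtr, variance_target=pca_variance,
                          n_components=pca_components)
            Xtr = pca_transform(pca, Xtr)
            Xva = pca_transform(pca, Xva)
        model = train_model(Xtr, y[tr], replace(config, seed=config.seed + k))
        probs = model.predict_proba(Xva)
        pooled_probs[va] = probs
        fold_metrics.append(evaluate_predictions(probs, y[va], B=bootstrap_B,
                                                 seed=config.seed + k))
        fold_indices.append(va)
    pooled = evaluate_predictions(pooled_probs, y, B=bootstrap_B, seed=config.seed)
    return CrossValResult(
        fold_metrics=fold_metrics,
        pooled=pooled,
        fold_indices=fold_indices,
        pooled_probabilities=pooled_probs,
        labels=y,
    )
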