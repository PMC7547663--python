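"""Binary classifiers for Gla-site prediction.

The primary model is a single-hidden-layer multilayer perceptron (logistic
activations); L2-regularized logistic regression and a random forest serve as
baselines. All three are backed by scikit-learn estimators behind a small
train/predict surface with explicit seeding and a configurable decision
threshold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

MODEL_KINDS = ("MLP", "LR", "RF")


@dataclass(frozen=True)
class ModelConfig:
    """Classifier configuration.

    The MLP uses one hidden layer of 100 units with logistic sigmoid
    activations by default; ``decision_threshold`` converts scores to labels
    (score >= threshold -> positive).
    """

    kind: str = "MLP"
    hidden_layer_sizes: tuple[int, ...] = (100,)
    activation: str = "logistic"
    solver: str = "adam"
    learning_rate_init: float = 1e-3
    max_iterations: int = 800
    n_trees: int = 100
    l2_strength: float = 1.0
    random_seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if len(self.hidden_layer_sizes) < 1 or min(self.hidden_layer_sizes) < 1:
            raise ValueError("at least one hidden layer with >= 1 unit is required")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclass
class TrainedModel:
    """A fitted classifier plus its configuration snapshot."""

    kind: str
    estimator: object
    config: ModelConfig
    n_samples: int
    n_features: int
    seed: int


def _build_estimator(config: ModelConfig):
    if config.kind == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=config.hidden_layer_sizes,
            activation=config.activation,
            solver=config.solver,
            learning_rate_init=config.learning_rate_init,
            max_iter=config.max_iterations,
            random_state=config.random_seed,
        )
    if config.kind == "LR":
        return LogisticRegression(
            C=config.l2_strength,
            max_iter=max(config.max_iterations, 1000),
            random_state=config.random_seed,
        )
    return RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.random_seed
    )


def train(features: np.ndarray, labels: np.ndarray, config: ModelConfig | None = None) -> TrainedModel:
    """Fit a classifier on scaled features; deterministic for a fixed seed."""
    config = config or ModelConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in sample count")
    if X.shape[0] < 2:
        raise ValueError("at least two samples are required")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training labels")
    if np.isnan(X).any():
        raise ValueError("features contain NaN values")
    estimator = _build_estimator(config)
    estimator.fit(X, y)
    return TrainedModel(
        kind=config.kind,
        estimator=estimator,
        config=config,
        n_samples=X.shape[0],
        n_features=X.shape[1],
        seed=config.random_seed,
    )


def _check_features(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features per sample, got shape {X.shape}"
        )
    return X


def predict_score(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Positive-class probabilities in [0, 1]."""
    X = _check_features(model, features)
    proba = model.estimator.predict_proba(X)
    positive_col = list(model.estimator.classes_).index(1)
    return proba[:, positive_col]


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Binary labels: 1 iff score >= decision threshold (ties positive)."""
    scores = predict_score(model, features)
    return (scores >= model.config.decision_threshold).astype(int)


def save_model(model: TrainedModel, path: str | Path, feature_names: list[str] | None = None) -> None:
    """Serialize estimator (joblib) plus a JSON sidecar with the config."""
    path = Path(path)
    joblib.dump(model, path)
    layout_hash = (
        hashlib.sha256("\n".join(feature_names).encode()).hexdigest()
        if feature_names
        else None
    )
    sidecar = {
        "format_version": 1,
        "kind": model.kind,
        "config": asdict(model.config),
        "n_samples": model.n_samples,
        "n_features": model.n_features,
        "seed": model.seed,
        "feature_layout_sha256": layout_hash,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
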