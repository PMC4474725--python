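"""Uniform train / predict-probability contract over seven classifiers.

The benchmarked learners are LDA, QDA, elastic-net logistic regression (LR),
RBF-kernel SVM, random forest (RF), AdaBoost (ADABOOST) and a single-hidden-
layer MLP.  Standard scikit-learn estimators are used wherever they implement
the required model; the MLP is a small seeded softmax network trained on the
negative log-likelihood with both L1 and L2 penalties, since that combination
is part of its definition here.

Every learner is consumed through :func:`train` / :func:`predict_proba`, which
guarantee sorted class order, rows-sum-to-one probabilities, and seeded
determinism.  Scale-sensitive learners (SVM, LR, MLP) get train-set
standardisation inside the contract; tree ensembles do not.

Hyperparameter grids (:class:`ParamGrid`) are first-class data: each kind has
a fixed schema of tunable axes, while the numeric candidate values are
configuration defaults that callers may override.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "KINDS",
    "ClassifierSpec",
    "ParamGrid",
    "PredictionResult",
    "TrainedModel",
    "default_grid",
    "train",
    "predict_proba",
    "softmax",
    "save_model",
    "load_model",
]

KINDS = ("LDA", "QDA", "LR", "SVM_RBF", "RF", "ADABOOST", "MLP")

#: Tunable axes per kind.  The discriminant-analysis models have none.
_GRID_SCHEMA: dict[str, tuple[str, ...]] = {
    "LDA": (),
    "QDA": (),
    "LR": ("l1_ratio", "C"),
    "SVM_RBF": ("C", "gamma"),
    "RF": ("n_estimators", "max_features", "max_depth", "min_samples_leaf"),
    "ADABOOST": ("n_estimators", "max_features", "max_depth", "learning_rate"),
    "MLP": ("hidden_units", "l1", "l2", "learning_rate"),
}

# Candidate values are configuration defaults, chosen as conventional
# log-spaced ranges; SVM gamma values are multiples of 1/n_features.
_DEFAULT_AXES: dict[str, dict[str, list]] = {
    "LDA": {},
    "QDA": {},
    "LR": {"l1_ratio": [0.0, 0.5, 1.0], "C": [0.01, 0.1, 1.0, 10.0]},
    "SVM_RBF": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.1, 1.0, 10.0]},
    "RF": {
        "n_estimators": [100, 300],
        "max_features": ["sqrt", 0.5],
        "max_depth": [None, 5, 10],
        "min_samples_leaf": [1, 5],
    },
    "ADABOOST": {
        "n_estimators": [50, 200],
        "max_features": ["sqrt", None],
        "max_depth": [1, 3],
        "learning_rate": [0.1, 1.0],
    },
    "MLP": {
        "hidden_units": [10, 50],
        "l1": [0.0, 1e-4],
        "l2": [0.0, 1e-4],
        "learning_rate": [1e-3, 1e-2],
    },
}


@dataclass(frozen=True)
class ParamGrid:
    kind: str
    axes: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        schema = _GRID_SCHEMA[self.kind]
        for name, values in self.axes.items():
            if name not in schema:
                raise ValueError(
                    f"{name!r} is not a tunable axis of {self.kind} (axes: {schema})"
                )
            if len(values) == 0:
                raise ValueError(f"axis {name!r} has no candidate values")

    def configurations(self) -> list[dict]:
        """Cartesian product of the axes, in deterministic order."""
        names = sorted(self.axes)
        out = [{}]
        for name in names:
            out = [{**c, name: v} for c in out for v in self.axes[name]]
        return out


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        schema = _GRID_SCHEMA[self.kind]
        for name in self.hyperparameters:
            if name not in schema:
                raise ValueError(
                    f"{name!r} is not a hyperparameter of {self.kind} (axes: {schema})"
                )


@dataclass
class PredictionResult:
    """Per-sample class probabilities with the sorted class order."""

    probabilities: np.ndarray
    class_order: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        self.probabilities = p

    def predicted_labels(self) -> np.ndarray:
        """Argmax labels; ties resolve to the earliest (sorted) class."""
        return self.class_order[np.argmax(self.probabilities, axis=1)]


def default_grid(kind: str) -> ParamGrid:
    if kind not in KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return ParamGrid(kind=kind, axes=dict(_DEFAULT_AXES[kind]))


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax; the posterior form of multinomial logistic regression."""
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Seeded single-hidden-layer MLP (softmax output, NLL + L1 + L2 loss, Adam,
# early stopping on a 10 % validation split).


class _SeededMLP(ClassifierMixin, BaseEstimator):
    def __init__(self, hidden_units=50, l1=0.0, l2=1e-4, learning_rate=1e-2,
                 max_epochs=300, patience=25, seed=0):
        self.hidden_units = int(hidden_units)
        self.l1 = float(l1)
        self.l2 = float(l2)
        self.learning_rate = float(learning_rate)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.seed = int(seed)

    def _forward(self, X):
        h = np.tanh(X @ self.W1 + self.b1)
        return h, softmax(h @ self.W2 + self.b2)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = len(self.classes_)
        rng = np.random.default_rng(self.seed)

        # 10 % validation split for early stopping (at least one sample)
        perm = rng.permutation(n)
        n_val = max(1, n // 10)
        val, tr = perm[:n_val], perm[n_val:]
        if len(tr) == 0:
            tr = perm
        Xt, yt, Xv, yv = X[tr], y_idx[tr], X[val], y_idx[val]

        h = self.hidden_units
        self.W1 = rng.normal(0, 1.0 / np.sqrt(d), (d, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(h), (h, k))
        self.b2 = np.zeros(k)

        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        onehot = np.eye(k)[yt]

        best_val = np.inf
        best_params = [p.copy() for p in params]
        since_best = 0
        for epoch in range(1, self.max_epochs + 1):
            hid, prob = self._forward(Xt)
            dscore = (prob - onehot) / len(Xt)
            grads = [None] * 4
            grads[2] = hid.T @ dscore + self.l2 * 2 * self.W2 + self.l1 * np.sign(self.W2)
            grads[3] = dscore.sum(axis=0)
            dhid = (dscore @ self.W2.T) * (1 - hid**2)
            grads[0] = Xt.T @ dhid + self.l2 * 2 * self.W1 + self.l1 * np.sign(self.W1)
            grads[1] = dhid.sum(axis=0)
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g**2
                mhat = m[i] / (1 - beta1**epoch)
                vhat = v[i] / (1 - beta2**epoch)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

            _, pv = self._forward(Xv)
            val_nll = -np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12))
            if val_nll < best_val - 1e-6:
                best_val = val_nll
                best_params = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.W1, self.b1, self.W2, self.b2 = best_params
        return self

    def predict_proba(self, X):
        _, prob = self._forward(np.asarray(X, dtype=float))
        return prob

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _build_estimator(spec: ClassifierSpec, n_features: int):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis(), False
    if spec.kind == "QDA":
        # small diagonal shrinkage guards singular per-class covariances in
        # high-dimensional feature spaces
        return QuadraticDiscriminantAnalysis(reg_param=1e-6), False
    if spec.kind == "LR":
        return (
            LogisticRegression(
                solver="saga",
                l1_ratio=hp.get("l1_ratio", 0.5),
                C=hp.get("C", 1.0),
                max_iter=5000,
                random_state=seed,
            ),
            True,
        )
    if spec.kind == "SVM_RBF":
        gamma = hp.get("gamma", 1.0)
        if isinstance(gamma, (int, float)):
            gamma = float(gamma) / n_features  # grid values are multiples of 1/d
        return (
            SVC(
                kernel="rbf",
                C=hp.get("C", 1.0),
                gamma=gamma,
                probability=True,
                random_state=seed,
            ),
            True,
        )
    if spec.kind == "RF":
        return (
            RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 100),
                max_features=hp.get("max_features", "sqrt"),
                max_depth=hp.get("max_depth", None),
                min_samples_leaf=hp.get("min_samples_leaf", 1),
                random_state=seed,
            ),
            False,
        )
    if spec.kind == "ADABOOST":
        return (
            AdaBoostClassifier(
                estimator=DecisionTreeClassifier(
                    max_depth=hp.get("max_depth", 1),
                    max_features=hp.get("max_features", None),
                    random_state=seed,
                ),
                n_estimators=hp.get("n_estimators", 50),
                learning_rate=hp.get("learning_rate", 1.0),
                random_state=seed,
            ),
            False,
        )
    if spec.kind == "MLP":
        return (
            _SeededMLP(
                hidden_units=hp.get("hidden_units", 50),
                l1=hp.get("l1", 0.0),
                l2=hp.get("l2", 1e-4),
                learning_rate=hp.get("learning_rate", 1e-2),
                seed=seed,
            ),
            True,
        )
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    classes_: np.ndarray
    n_features: int


def _as_array(features) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.labels
    return np.asarray(features, dtype=float), None


def train(spec: ClassifierSpec, features: FeatureMatrix) -> TrainedModel:
    """Fit a classifier; deterministic given (spec, seed, features)."""
    X, y = features.values, features.labels
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training needs >= 2 classes, got {len(classes)}")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 training samples")
    est, scale = _build_estimator(spec, X.shape[1])
    if scale:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, classes_=classes, n_features=X.shape[1])


def predict_proba(model: TrainedModel, features) -> PredictionResult:
    """Class probabilities in sorted-class column order; rows sum to one."""
    X, _ = _as_array(features)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model was trained on {model.n_features} features, got {X.shape[1]}"
        )
    p = model.estimator.predict_proba(X)
    p = np.clip(p, 0.0, None)
    p = p / p.sum(axis=1, keepdims=True)
    est = model.estimator
    inner = est.named_steps["clf"] if isinstance(est, Pipeline) else est
    order = np.argsort(inner.classes_.astype(str)) if not np.array_equal(
        inner.classes_, model.classes_
    ) else np.arange(len(model.classes_))
    return PredictionResult(probabilities=p[:, order], class_order=model.classes_)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise a trained model; spec and seed travel in a JSON sidecar."""
    path = Path(path)
    with open(path, "wb") as f:
        pickle.dump(model, f)
    meta = {
        "kind": model.spec.kind,
        "hyperparameters": {k: v for k, v in model.spec.hyperparameters.items()},
        "seed": model.spec.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as f:
        return pickle.load(f)
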