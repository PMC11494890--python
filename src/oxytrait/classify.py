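"""Ternary and binary oxygen-phenotype classifiers.

Two model families, matching the published training protocol:

* L2-regularized multinomial logistic regression (C = 100,
  max_iter = 10,000), fit with scikit-learn;
* a single-hidden-layer perceptron (input -> 512 ReLU units -> softmax
  output) trained by mini-batch gradient descent (batch 16, learning rate
  1e-4, at most 100 epochs) with L2 weight decay; after every epoch the
  validation balanced accuracy is computed and the weights of the best
  epoch are returned.

Features are z-scored with statistics fitted on the training split only;
the standardizer and the feature-schema hash travel with the model so a
model refuses feature matrices built under a different schema.
Evaluation is class-balanced accuracy: the unweighted mean of per-class
recalls, whose chance level is 1/(number of classes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, confusion_matrix

from .features import FeatureMatrix, FeatureSpec

__all__ = [
    "TrainConfig",
    "Standardizer",
    "ClassifierModel",
    "EvalReport",
    "fit_standardizer",
    "apply_standardizer",
    "train_logistic",
    "train_mlp",
    "predict_proba",
    "predict",
    "balanced_accuracy",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for both model families (published defaults)."""

    model_kind: str = "logistic"
    l2_C: float = 100.0
    max_iter: int = 10_000
    hidden_units: int = 512
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    weight_decay: float = 1e-4
    optimizer: str = "sgd"
    class_weight: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("logistic", "mlp"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.l2_C <= 0 or self.learning_rate <= 0:
            raise ValueError("l2_C and learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class Standardizer:
    """Per-feature z-scoring; zero-variance columns pass through unscaled."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"standardizer fitted on {self.mean.size} features, "
                f"got {X.shape[1]}"
            )
        return (X - self.mean) / self.scale


def fit_standardizer(X: FeatureMatrix | np.ndarray) -> Standardizer:
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    if values.size == 0:
        raise ValueError("cannot fit a standardizer on an empty matrix")
    mean = values.mean(axis=0)
    scale = values.std(axis=0)
    scale[scale == 0] = 1.0
    return Standardizer(mean=mean, scale=scale)


def apply_standardizer(std: Standardizer, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    return std.transform(values)


@dataclass
class ClassifierModel:
    """A trained classifier plus everything needed to reapply it."""

    classes: list[str]
    feature_schema: dict
    standardizer: Standardizer
    kind: str
    params: dict[str, np.ndarray]
    config: TrainConfig
    selected_epoch: int | None = None
    val_history: list[float] | None = None  # per-epoch validation balanced accuracy

    @property
    def schema_hash(self) -> str | None:
        return self.feature_schema.get("schema_hash")


@dataclass
class EvalReport:
    """Class-balanced evaluation summary."""

    balanced_accuracy: float
    per_class_recall: dict[str, float]
    confusion: np.ndarray
    classes: list[str]
    n: int


def _schema_for(X: FeatureMatrix | np.ndarray) -> dict:
    if isinstance(X, FeatureMatrix):
        return {
            "kind": X.spec.kind,
            "k": X.spec.k,
            "normalization": X.spec.normalization,
            "schema_hash": X.schema_hash,
            "n_features": len(X.feature_names),
        }
    X = np.asarray(X)
    return {"kind": "raw", "k": None, "normalization": None,
            "schema_hash": None, "n_features": X.shape[1]}


def _check_schema(model: ClassifierModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        if model.schema_hash is not None and X.schema_hash != model.schema_hash:
            raise ValueError(
                "feature schema mismatch: model was trained under "
                f"{model.schema_hash}, matrix has {X.schema_hash}"
            )
        values = X.values
    else:
        values = np.asarray(X, dtype=float)
    if values.shape[1] != model.feature_schema["n_features"]:
        raise ValueError(
            f"model expects {model.feature_schema['n_features']} features, "
            f"got {values.shape[1]}"
        )
    return values


def _validate_labels(y: Sequence[str]) -> np.ndarray:
    y = np.asarray(y, dtype=object)
    if len(set(y)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    return y


def train_logistic(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[str],
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Fit the L2-regularized multinomial logistic model."""
    config = config or TrainConfig(model_kind="logistic")
    y = _validate_labels(y)
    schema = _schema_for(X)
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    std = fit_standardizer(values)
    Xs = std.transform(values)
    clf = LogisticRegression(  # default penalty is the L2 norm
        C=config.l2_C,
        max_iter=config.max_iter,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    clf.fit(Xs, y)
    # reorder to alphabetical class order (sklearn already sorts, asserted)
    classes = [str(c) for c in clf.classes_]
    assert classes == sorted(classes)
    coef = clf.coef_
    intercept = clf.intercept_
    if len(classes) == 2:  # expand binary coef to per-class rows
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    return ClassifierModel(
        classes=classes,
        feature_schema=schema,
        standardizer=std,
        kind="logistic",
        params={"coef": coef, "intercept": intercept},
        config=config,
    )


# --- multilayer perceptron -------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _mlp_forward(params: Mapping[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    h = np.maximum(X @ params["W1"] + params["b1"], 0.0)
    return _softmax(h @ params["W2"] + params["b2"])


def train_mlp(
    X_train: FeatureMatrix | np.ndarray,
    y_train: Sequence[str],
    X_val: FeatureMatrix | np.ndarray,
    y_val: Sequence[str],
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Train the single-hidden-layer perceptron with epoch selection.

    After each epoch the balanced accuracy on the validation set is
    computed; the returned model carries the weights of the best epoch
    (earliest epoch on ties) and records it as ``selected_epoch``.
    """
    config = config or TrainConfig(model_kind="mlp")
    y_train = _validate_labels(y_train)
    y_val = np.asarray(y_val, dtype=object)
    if y_val.size == 0:
        raise ValueError("validation set must be non-empty")
    schema = _schema_for(X_train)
    Xt = X_train.values if isinstance(X_train, FeatureMatrix) else np.asarray(X_train, float)
    Xv = X_val.values if isinstance(X_val, FeatureMatrix) else np.asarray(X_val, float)
    classes = sorted(set(y_train))
    unknown_val = set(y_val) - set(classes)
    if unknown_val:
        raise ValueError(f"validation labels {sorted(unknown_val)} unseen in training")
    class_index = {c: i for i, c in enumerate(classes)}
    yt = np.array([class_index[c] for c in y_train])

    std = fit_standardizer(Xt)
    Xt = std.transform(Xt)
    Xv = std.transform(Xv)

    rng = np.random.default_rng(config.seed)
    d, h, c = Xt.shape[1], config.hidden_units, len(classes)
    params = {
        "W1": rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
        "b1": np.zeros(h),
        "W2": rng.normal(0.0, np.sqrt(2.0 / h), size=(h, c)),
        "b2": np.zeros(c),
    }
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    adam_t = 0
    lr, wd = config.learning_rate, config.weight_decay
    n = Xt.shape[0]

    best = {"epoch": None, "ba": -np.inf, "params": None}
    history: list[float] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xt[idx], yt[idx]
            z1 = xb @ params["W1"] + params["b1"]
            a1 = np.maximum(z1, 0.0)
            probs = _softmax(a1 @ params["W2"] + params["b2"])
            delta2 = probs.copy()
            delta2[np.arange(len(yb)), yb] -= 1.0
            delta2 /= len(yb)
            grads = {
                "W2": a1.T @ delta2 + wd * params["W2"],
                "b2": delta2.sum(axis=0),
            }
            delta1 = (delta2 @ params["W2"].T) * (z1 > 0)
            grads["W1"] = xb.T @ delta1 + wd * params["W1"]
            grads["b1"] = delta1.sum(axis=0)
            if config.optimizer == "adam":
                adam_t += 1
                b1_, b2_ = 0.9, 0.999
                for k in params:
                    adam_m[k] = b1_ * adam_m[k] + (1 - b1_) * grads[k]
                    adam_v[k] = b2_ * adam_v[k] + (1 - b2_) * grads[k] ** 2
                    mhat = adam_m[k] / (1 - b1_**adam_t)
                    vhat = adam_v[k] / (1 - b2_**adam_t)
                    params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            else:
                for k in params:
                    params[k] -= lr * grads[k]
        val_pred = [classes[i] for i in _mlp_forward(params, Xv).argmax(axis=1)]
        ba = balanced_accuracy_score(y_val, val_pred)
        history.append(float(ba))
        if ba > best["ba"]:
            best = {"epoch": epoch, "ba": ba,
                    "params": {k: v.copy() for k, v in params.items()}}

    return ClassifierModel(
        classes=classes,
        feature_schema=schema,
        standardizer=std,
        kind="mlp",
        params=best["params"],
        config=config,
        selected_epoch=best["epoch"],
        val_history=history,
    )


# --- prediction & evaluation ----------------------------------------------

def predict_proba(model: ClassifierModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) in ``model.classes`` order."""
    values = _check_schema(model, X)
    Xs = model.standardizer.transform(values)
    if model.kind == "logistic":
        logits = Xs @ model.params["coef"].T + model.params["intercept"]
        return _softmax(logits)
    return _mlp_forward(model.params, Xs)


def predict(model: ClassifierModel, X: FeatureMatrix | np.ndarray) -> list[str]:
    """Argmax labels; ties break toward the alphabetically first class."""
    probs = predict_proba(model, X)
    # classes are stored sorted, and argmax returns the first maximum,
    # which is therefore the alphabetically first class on ties
    return [model.classes[i] for i in probs.argmax(axis=1)]


def balanced_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Unweighted mean of per-class recalls."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValueError("y_true is empty")
    stray = set(y_pred) - set(y_true)
    if stray:
        raise ValueError(f"predicted labels {sorted(stray)} not in the class set")
    return float(balanced_accuracy_score(y_true, y_pred))


def evaluate(
    model: ClassifierModel, X: FeatureMatrix | np.ndarray, y: Sequence[str]
) -> EvalReport:
    y = np.asarray(y, dtype=object)
    y_pred = np.asarray(predict(model, X), dtype=object)
    classes = model.classes
    conf = confusion_matrix(y, y_pred, labels=classes)
    support = conf.sum(axis=1)
    present = support > 0
    recalls = {
        c: float(conf[i, i] / support[i])
        for i, c in enumerate(classes)
        if present[i]
    }
    ba = float(np.mean(list(recalls.values())))
    return EvalReport(
        balanced_accuracy=ba,
        per_class_recall=recalls,
        confusion=conf,
        classes=list(classes),
        n=int(y.size),
    )


# --- serialization ---------------------------------------------------------

def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Serialize to JSON; MLP weights go to a sidecar ``.npz`` blob."""
    path = Path(path)
    doc = {
        "classes": model.classes,
        "feature_schema": model.feature_schema,
        "kind": model.kind,
        "config": asdict(model.config),
        "selected_epoch": model.selected_epoch,
        "val_history": model.val_history,
        "standardizer": {
            "mean": model.standardizer.mean.tolist(),
            "scale": model.standardizer.scale.tolist(),
        },
    }
    if model.kind == "logistic":
        doc["params"] = {k: v.tolist() for k, v in model.params.items()}
    else:
        blob = Path(str(path) + ".weights.npz")
        np.savez(blob, **model.params)
        doc["weights_blob"] = blob.name
    path.write_text(json.dumps(doc) + "\n")


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    doc = json.loads(path.read_text())
    std = Standardizer(
        mean=np.asarray(doc["standardizer"]["mean"], float),
        scale=np.asarray(doc["standardizer"]["scale"], float),
    )
    if doc["kind"] == "logistic":
        params = {k: np.asarray(v, float) for k, v in doc["params"].items()}
    else:
        with np.load(path.parent / doc["weights_blob"]) as npz:
            params = {k: npz[k] for k in npz.files}
    return ClassifierModel(
        classes=list(doc["classes"]),
        feature_schema=dict(doc["feature_schema"]),
        standardizer=std,
        kind=doc["kind"],
        params=params,
        config=TrainConfig(**doc["config"]),
        selected_epoch=doc["selected_epoch"],
        val_history=doc.get("val_history"),
    )
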