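"""The 16-configuration classifier benchmark over 1-D global feature vectors.

The registry holds sixteen named configurations spanning six families:

====== ======== ==============================================================
name   family   parameters
====== ======== ==============================================================
LSVM     svm    linear SVM, C = 1
LSVM_SGD svm    linear SVM trained by SGD, hinge loss, elastic-net penalty
KNN39    knn    k-nearest neighbours, k = 39 (square-root rule on n = 1547)
KNN99    knn    k-nearest neighbours, k = 99
DT1      tree   decision tree, at most 3000 nodes
DT2      tree   decision tree, at most 100,000 nodes
RF1      forest 75 trees, 300 nodes, 10 candidate features per split
RF2      forest 50 trees, 1000 nodes, 50 candidate features per split
CNN1-4   cnn    1-D convnets: 2 or 3 conv/ReLU/pool blocks, softmax head;
                CNN1/2: Adadelta, 50 epochs, batch 356;
                CNN3/4: RMSProp, 150 epochs, batch 128
DNN1-4   dnn    dense nets: structure 1 = 3 dense layers (ReLU, tanh, tanh)
                + dropout; structure 2 = 4 dense layers, all ReLU + dropout;
                DNN1/2: RMSProp, batch 518; DNN3/4: SGD, batch 356;
                500 epochs for all
====== ======== ==============================================================

Because the networks consume the stacked 1-D feature arrays (not images),
the CNNs convolve along the feature axis.  Scale-sensitive families (svm,
knn, cnn, dnn) see z-score standardized features, with the standardization
fitted on the training split only; trees and forests consume raw features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from ..dataset import CLASSES
from . import nn

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "REGISTRY_NAMES",
    "knn_k",
    "build_config",
    "train",
    "predict",
]

REGISTRY_NAMES = (
    "LSVM", "LSVM_SGD", "KNN39", "KNN99", "DT1", "DT2", "RF1", "RF2",
    "CNN1", "CNN2", "CNN3", "CNN4", "DNN1", "DNN2", "DNN3", "DNN4",
)


def knn_k(n_train: int) -> int:
    """Neighbour count by the square-root rule: nearest odd integer to
    sqrt(n_train), ties resolved downward (odd k avoids two-class vote ties).
    """
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    s = math.sqrt(n_train)
    lo = int(math.floor(s))
    if lo % 2 == 0:
        lo -= 1
    lo = max(lo, 1)
    hi = lo + 2
    return lo if (s - lo) <= (hi - s) else hi


@dataclass(frozen=True)
class ClassifierConfig:
    """One named, immutable classifier configuration."""

    name: str
    family: str  # svm | sgd_svm | knn | tree | forest | cnn | dnn
    hyper: Mapping[str, object]
    train_params: Mapping[str, object]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hyper", MappingProxyType(dict(self.hyper)))
        object.__setattr__(self, "train_params", MappingProxyType(dict(self.train_params)))

    # mapping proxies are not picklable; serialize as plain dicts
    def __getstate__(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "hyper": dict(self.hyper),
            "train_params": dict(self.train_params),
            "seed": self.seed,
        }

    def __setstate__(self, state: dict) -> None:
        for key, value in state.items():
            object.__setattr__(self, key, value)
        self.__post_init__()


_CNN_FILTERS = {1: (32, 64), 2: (32, 64, 128)}   # structure -> conv filters
_DNN_WIDTHS = {1: (256, 128, 64), 2: (256, 128, 64, 64)}

_REGISTRY_SPECS: dict[str, tuple[str, dict, dict]] = {
    "LSVM": ("svm", {"C": 1.0}, {}),
    "LSVM_SGD": ("sgd_svm", {"loss": "hinge", "penalty": "elasticnet"}, {}),
    "KNN39": ("knn", {"k": 39}, {}),
    "KNN99": ("knn", {"k": 99}, {}),
    "DT1": ("tree", {"max_nodes": 3000}, {}),
    "DT2": ("tree", {"max_nodes": 100_000}, {}),
    "RF1": ("forest", {"n_trees": 75, "max_nodes": 300, "max_features": 10}, {}),
    "RF2": ("forest", {"n_trees": 50, "max_nodes": 1000, "max_features": 50}, {}),
    "CNN1": ("cnn", {"structure": 1, "kernel": 3, "pool": 2},
             {"optimizer": "adadelta", "epochs": 50, "batch_size": 356}),
    "CNN2": ("cnn", {"structure": 2, "kernel": 3, "pool": 2},
             {"optimizer": "adadelta", "epochs": 50, "batch_size": 356}),
    "CNN3": ("cnn", {"structure": 1, "kernel": 3, "pool": 2},
             {"optimizer": "rmsprop", "epochs": 150, "batch_size": 128}),
    "CNN4": ("cnn", {"structure": 2, "kernel": 3, "pool": 2},
             {"optimizer": "rmsprop", "epochs": 150, "batch_size": 128}),
    "DNN1": ("dnn", {"structure": 1, "dropout": 0.5},
             {"optimizer": "rmsprop", "epochs": 500, "batch_size": 518}),
    "DNN2": ("dnn", {"structure": 2, "dropout": 0.5},
             {"optimizer": "rmsprop", "epochs": 500, "batch_size": 518}),
    "DNN3": ("dnn", {"structure": 1, "dropout": 0.5},
             {"optimizer": "sgd", "epochs": 500, "batch_size": 356}),
    "DNN4": ("dnn", {"structure": 2, "dropout": 0.5},
             {"optimizer": "sgd", "epochs": 500, "batch_size": 356}),
}


def build_config(name: str, seed: int = 0) -> ClassifierConfig:
    """Construct one of the 16 registry configurations by name."""
    if name not in _REGISTRY_SPECS:
        raise ValueError(
            f"unknown classifier {name!r}; valid names: {', '.join(REGISTRY_NAMES)}"
        )
    family, hyper, train_params = _REGISTRY_SPECS[name]
    return ClassifierConfig(name=name, family=family, hyper=hyper,
                            train_params=train_params, seed=seed)


@dataclass
class TrainedModel:
    """A fitted configuration plus everything needed to score new vectors."""

    config: ClassifierConfig
    estimator: object
    scaler: StandardScaler | None
    class_order: tuple[str, ...]
    model_classes: tuple[str, ...]  # classes seen in training, estimator order
    n_features: int


_SCALED_FAMILIES = {"svm", "sgd_svm", "knn", "cnn", "dnn"}


def _class_order(labels: Sequence[str]) -> tuple[str, ...]:
    present = set(labels)
    if present <= set(CLASSES):
        return CLASSES
    return tuple(sorted(present))


def _build_network(config: ClassifierConfig, n_features: int, n_classes: int) -> nn.Network:
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    if config.family == "cnn":
        length, channels = n_features, 1
        for filters in _CNN_FILTERS[config.hyper["structure"]]:
            layers.append(nn.Conv1D(channels, filters, config.hyper["kernel"], rng))
            layers.append(nn.ReLU())
            layers.append(nn.MaxPool1D(config.hyper["pool"]))
            length = (length - config.hyper["kernel"] + 1) // config.hyper["pool"]
            channels = filters
        layers.append(nn.Flatten())
        layers.append(nn.Dense(length * channels, n_classes, rng))
    else:  # dnn
        widths = _DNN_WIDTHS[config.hyper["structure"]]
        activations = (
            [nn.ReLU] + [nn.Tanh] * (len(widths) - 1)
            if config.hyper["structure"] == 1
            else [nn.ReLU] * len(widths)
        )
        prev = n_features
        for width, act in zip(widths, activations):
            layers.append(nn.Dense(prev, width, rng))
            layers.append(act())
            prev = width
        layers.append(nn.Dropout(config.hyper["dropout"]))
        layers.append(nn.Dense(prev, n_classes, rng))
    return nn.Network(layers, seed=config.seed)


class _NetEstimator:
    """Adapter giving the numpy networks a classes_/predict_proba surface."""

    def __init__(self, network: nn.Network, classes: np.ndarray) -> None:
        self.network = network
        self.classes_ = classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(X)


def train(
    config: ClassifierConfig,
    features: Sequence | np.ndarray,
    labels: Sequence[str],
) -> TrainedModel:
    """Fit one configuration; deterministic given ``config.seed``."""
    X = np.asarray(
        [f.values if hasattr(f, "values") else f for f in features], dtype=np.float64
    )
    if X.ndim != 2:
        raise ValueError("features must form a 2-D (n, L) array")
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("features and labels length mismatch")
    classes_present = np.unique(y)
    if len(classes_present) < 2 and config.family in ("svm", "sgd_svm", "cnn", "dnn"):
        raise ValueError(
            f"{config.name} needs at least 2 classes in the training data; "
            "a constant predictor is not a meaningful fallback for margin/NN models"
        )
    scaler = None
    Xs = X
    if config.family in _SCALED_FAMILIES:
        scaler = StandardScaler()
        Xs = scaler.fit_transform(X)
    seed, h = config.seed, config.hyper
    if config.family == "svm":
        est = LinearSVC(C=h["C"], random_state=seed)
        est.fit(Xs, y)
    elif config.family == "sgd_svm":
        est = SGDClassifier(loss=h["loss"], penalty=h["penalty"], random_state=seed)
        est.fit(Xs, y)
    elif config.family == "knn":
        k = h["k"]
        if k > len(X):
            warnings.warn(
                f"{config.name}: k={k} exceeds n_train={len(X)}; clamping k",
                stacklevel=2,
            )
            k = len(X)
        est = KNeighborsClassifier(n_neighbors=k)
        est.fit(Xs, y)
    elif config.family == "tree":
        est = DecisionTreeClassifier(max_leaf_nodes=h["max_nodes"], random_state=seed)
        est.fit(Xs, y)
    elif config.family == "forest":
        est = RandomForestClassifier(
            n_estimators=h["n_trees"],
            max_leaf_nodes=h["max_nodes"],
            max_features=min(h["max_features"], X.shape[1]),
            random_state=seed,
        )
        est.fit(Xs, y)
    elif config.family in ("cnn", "dnn"):
        order = _class_order(y)
        classes = np.asarray([c for c in order if c in classes_present])
        index = {c: i for i, c in enumerate(classes)}
        y_idx = np.asarray([index[c] for c in y])
        x_in = Xs[:, :, None] if config.family == "cnn" else Xs
        net = _build_network(config, X.shape[1], len(classes))
        net.fit(
            x_in.astype(np.float32), y_idx, len(classes),
            epochs=config.train_params["epochs"],
            batch_size=config.train_params["batch_size"],
            optimizer=config.train_params["optimizer"],
        )
        est = _NetEstimator(net, classes)
    else:
        raise ValueError(f"unknown family {config.family!r}")
    return TrainedModel(
        config=config,
        estimator=est,
        scaler=scaler,
        class_order=_class_order(y),
        model_classes=tuple(est.classes_),
        n_features=X.shape[1],
    )


def _raw_scores(model: TrainedModel, Xs: np.ndarray) -> np.ndarray:
    """(n, n_model_classes) scores summing to 1 per row."""
    est = model.estimator
    if hasattr(est, "predict_proba"):
        if isinstance(est, _NetEstimator) and model.config.family == "cnn":
            return est.predict_proba(Xs[:, :, None].astype(np.float32))
        return est.predict_proba(Xs)
    # margin models: softmax over decision values gives rankable,
    # normalized scores (monotone in the margins)
    d = est.decision_function(Xs)
    if d.ndim == 1:
        d = np.stack([-d, d], axis=1)
    d = d - d.max(axis=1, keepdims=True)
    e = np.exp(d)
    return e / e.sum(axis=1, keepdims=True)


def predict(
    model: TrainedModel, features: Sequence | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-element score rows over ``model.class_order``.

    The score row spans the full class order (13 columns for schema-labelled
    data); classes absent at training score 0.  The label is the argmax of
    the score row, ties broken by class order.
    """
    X = np.asarray(
        [f.values if hasattr(f, "values") else f for f in features], dtype=np.float64
    )
    if X.size == 0:
        return np.asarray([], dtype=object), np.zeros((0, len(model.class_order)))
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected (n, {model.n_features}) feature array, got {X.shape}"
        )
    Xs = model.scaler.transform(X) if model.scaler is not None else X
    raw = _raw_scores(model, Xs)
    scores = np.zeros((len(X), len(model.class_order)))
    col = {c: i for i, c in enumerate(model.class_order)}
    for j, c in enumerate(model.model_classes):
        scores[:, col[c]] = raw[:, j]
    idx = scores.argmax(axis=1)
    labels = np.asarray([model.class_order[i] for i in idx], dtype=object)
    return labels, scores
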