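"""Comparison classifiers: KNN and SVM on flattened windows, CNN-LSTM.

All baselines consume exactly the same windowed sequences as FASPP-GRU
(flattened to 11 x 208 feature vectors for the non-neural models), so
per-condition comparisons are paired.  KNN uses Euclidean distance and
breaks vote ties towards the lowest class index; the SVM is an RBF-kernel
one-vs-rest machine.  Hyperparameters are selected on the validation
split by accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from eitgest.nn.models import CNNLSTM, CNNLSTMConfig
from eitgest.nn.training import TrainConfig, train_classifier


@dataclass
class BaselineConfig:
    """Tuning grids for the classical baselines."""

    knn_grid: tuple = (1, 3, 5, 7, 9)
    svm_c_grid: tuple = (1.0, 10.0, 100.0)
    svm_gamma_grid: tuple = ("scale",)
    standardize: bool = True

    def __post_init__(self):
        if any(k < 1 for k in self.knn_grid):
            raise ValueError("k must be positive")
        if any(c <= 0 for c in self.svm_c_grid):
            raise ValueError("C must be positive")


def _flatten(X):
    X = np.asarray(X, dtype=float)
    return X.reshape(len(X), -1)


def _check_train(y):
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: a single class")


class _FlatModel:
    """Fitted KNN/SVM wrapper exposing the common predict interface."""

    def __init__(self, estimator, scaler, chosen):
        self.estimator = estimator
        self.scaler = scaler
        self.chosen = chosen

    def predict(self, X):
        Z = _flatten(X)
        if self.scaler is not None:
            Z = self.scaler.transform(Z)
        return self.estimator.predict(Z)


def fit_knn(X_train, y_train, X_val, y_val, cfg: BaselineConfig | None = None):
    """Fit KNN with k selected on the validation split.

    scikit-learn's majority vote resolves ties towards the lowest class
    index, which is the documented deterministic tie-break.
    """
    cfg = cfg or BaselineConfig()
    _check_train(y_train)
    Ztr, Zva = _flatten(X_train), _flatten(X_val)
    scaler = None
    if cfg.standardize:
        scaler = StandardScaler().fit(Ztr)
        Ztr, Zva = scaler.transform(Ztr), scaler.transform(Zva)
    best = (-1.0, None, None)
    for k in cfg.knn_grid:
        if k > len(Ztr):
            continue
        est = KNeighborsClassifier(n_neighbors=k).fit(Ztr, y_train)
        acc = float((est.predict(Zva) == y_val).mean())
        if acc > best[0]:
            best = (acc, est, k)
    return _FlatModel(best[1], scaler, {"k": best[2], "val_acc": best[0]})


def fit_svm(X_train, y_train, X_val, y_val, cfg: BaselineConfig | None = None):
    """Fit an RBF SVM (one-vs-rest) with C/gamma selected on validation."""
    cfg = cfg or BaselineConfig()
    _check_train(y_train)
    Ztr, Zva = _flatten(X_train), _flatten(X_val)
    scaler = None
    if cfg.standardize:
        scaler = StandardScaler().fit(Ztr)
        Ztr, Zva = scaler.transform(Ztr), scaler.transform(Zva)
    best = (-1.0, None, None)
    for C in cfg.svm_c_grid:
        for gamma in cfg.svm_gamma_grid:
            est = SVC(
                C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovr"
            ).fit(Ztr, y_train)
            acc = float((est.predict(Zva) == y_val).mean())
            if acc > best[0]:
                best = (acc, est, (C, gamma))
    return _FlatModel(best[1], scaler, {"C_gamma": best[2], "val_acc": best[0]})


def fit_cnn_lstm(
    X_train,
    y_train,
    X_val,
    y_val,
    cfg: CNNLSTMConfig | None = None,
    train_cfg: TrainConfig | None = None,
):
    """Train the CNN-LSTM baseline; returns (model, learning curves)."""
    _check_train(y_train)
    model = CNNLSTM(cfg)
    history = train_classifier(model, X_train, y_train, X_val, y_val, train_cfg)
    return model, history
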