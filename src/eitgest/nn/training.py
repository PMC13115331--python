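"""Mini-batch training loop shared by the sequence classifiers.

Adam on the mean cross-entropy, early stopping on validation loss with
patience, per-epoch learning curves.  Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from eitgest.nn import core
from eitgest.nn.core import Adam, softmax_cross_entropy


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of predicted probabilities vs integer labels."""
    probs = np.asarray(probs, float)
    n = probs.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 15
    seed: int = 0

    @classmethod
    def from_model_config(cls, cfg) -> "TrainConfig":
        return cls(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            seed=cfg.seed,
        )


def _epoch_eval(model, X, y, batch_size):
    probs = model.predict_proba(X, batch_size)
    return cross_entropy(probs, y), float((probs.argmax(1) == y).mean())


def train_classifier(model, X_train, y_train, X_val, y_val, cfg: TrainConfig | None = None):
    """Train in place; returns the learning-curve history dict.

    Stops when the validation loss has not improved for ``patience``
    epochs (or at ``max_epochs``) and restores the best-validation
    weights.  ``history`` carries per-epoch train/val loss and accuracy.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    cfg = cfg or TrainConfig.from_model_config(model.cfg)
    X_train = np.asarray(X_train, dtype=core.DTYPE)
    X_val = np.asarray(X_val, dtype=core.DTYPE)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    n = len(X_train)
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        losses = []
        hits = 0
        for s in range(0, n, cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            logits = model.forward(X_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(1) == y_train[idx]).sum())
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(hits / n)
        val_loss, val_acc = _epoch_eval(model, X_val, y_val, cfg.batch_size)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return history
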