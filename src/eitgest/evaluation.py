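"""Evaluation: confusion matrices, accuracy/F1 metrics, per-condition
reports, Friedman comparison across models, and UMAP feature projection.

Accuracy is the multiclass trace/total (equivalently the micro-averaged
one-vs-rest form); precision, recall and F1 are computed one-vs-rest per
class with zero-denominator conventions set to 0, and F1 is aggregated
as the macro average over the 9 balanced classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from eitgest.protocol import GESTURES


@dataclass
class MetricReport:
    """Per-condition classification metrics (all values in [0, 1])."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    n: int
    condition: str = "none"
    model: str = ""

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "condition": self.condition,
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": {g: float(v) for g, v in zip(GESTURES, self.f1)},
        }


def confusion_matrix(y_true, y_pred, n_classes: int = 9) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def compute_metrics(cm: np.ndarray, condition: str = "none", model: str = "") -> MetricReport:
    """Derive accuracy and one-vs-rest precision/recall/F1 from counts."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return MetricReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1.mean()),
        n=total,
        condition=condition,
        model=model,
    )


def evaluate_under_conditions(predict_fn, datasets: dict, model_name: str = ""):
    """Evaluate one trained model on every condition's test set.

    ``datasets`` maps a condition label to ``(X, y)``; returns a dict of
    condition -> (MetricReport, confusion matrix).  Raises if a requested
    condition is missing its data.
    """
    out = {}
    for cond, data in datasets.items():
        if data is None:
            raise KeyError(f"missing dataset for condition {cond!r}")
        X, y = data
        y_pred = predict_fn(X)
        cm = confusion_matrix(y, y_pred)
        out[cond] = (compute_metrics(cm, condition=cond, model=model_name), cm)
    return out


def friedman_test(accuracies: np.ndarray):
    """Friedman rank test over paired blocks (rows) and models (columns).

    Returns ``(statistic, p_value)`` using mid-ranks for ties and the
    chi-square approximation with ``k - 1`` degrees of freedom.
    """
    A = np.asarray(accuracies, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("need a blocks x models matrix with >= 2 models")
    n, k = A.shape
    if n < 2:
        raise ValueError("need >= 2 paired blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, A)
    rbar = ranks.mean(axis=0)
    # tie-corrected statistic
    num = (n * (k + 1) / 2.0 - n * rbar) ** 2
    ss_total = ((ranks - (k + 1) / 2.0) ** 2).sum()
    if ss_total == 0:
        return 0.0, 1.0
    statistic = (k - 1) * (n * (rbar - (k + 1) / 2.0) ** 2).sum() / (ss_total / n)
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


def umap_projection(embeddings: np.ndarray, labels, seed: int = 0):
    """Project high-dimensional features to 2-D with UMAP (seeded).

    Returns the (n, 2) coordinates; requires at least 50 points.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if len(embeddings) < 50:
        raise ValueError("need at least 50 points for a stable projection")
    import umap  # deferred: numba-compiled import is slow

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return reducer.fit_transform(embeddings)


def nearest_centroid_regions(coords: np.ndarray, labels, grid_n: int = 120):
    """Classify a 2-D grid by nearest class centroid (decision-region
    rendering for UMAP plots; a visualisation approximation only)."""
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    cents = np.stack([coords[labels == c].mean(axis=0) for c in classes])
    pad = 0.05 * (coords.max(0) - coords.min(0) + 1e-9)
    lo, hi = coords.min(0) - pad, coords.max(0) + pad
    xs = np.linspace(lo[0], hi[0], grid_n)
    ys = np.linspace(lo[1], hi[1], grid_n)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    d = ((pts[:, None, :] - cents[None]) ** 2).sum(-1)
    region = classes[d.argmin(1)].reshape(grid_n, grid_n)
    return xs, ys, region


def plot_confusion(cm: np.ndarray, path, title: str = "") -> None:
    """Normalised confusion-matrix heatmap (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = cm / np.maximum(cm.sum(axis=1, keepdims=True), 1)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(frac, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(GESTURES)), GESTURES, rotation=45, ha="right")
    ax.set_yticks(range(len(GESTURES)), GESTURES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_umap(coords, labels, path, title: str = "") -> None:
    """Scatter of the UMAP projection over nearest-centroid regions (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys, region = nearest_centroid_regions(coords, labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(xs, ys, region, cmap="tab10", alpha=0.2, shading="auto", vmin=0, vmax=9)
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=labels, cmap="tab10", s=8, vmin=0, vmax=9)
    ax.set_title(title)
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=sc.cmap(sc.norm(i)), label=g)
        for i, g in enumerate(GESTURES)
    ]
    ax.legend(handles=handles, fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
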