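"""Metrics, confusion matrices, Friedman comparison, UMAP plumbing."""

import numpy as np
import pytest
from scipy import stats

from eitgest.evaluation import (
    compute_metrics,
    confusion_matrix,
    evaluate_under_conditions,
    friedman_test,
    nearest_centroid_regions,
)


def brute_force_metrics(y_true, y_pred, n_classes=9):
    """Independent per-pair counting oracle for accuracy and macro F1."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc = float((y_true == y_pred).mean())
    f1s = []
    for c in range(n_classes):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return acc, float(np.mean(f1s))


def test_compute_metrics_agrees_with_counting_oracle_on_100_vectors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(20, 200)
        y_true = rng.integers(0, 9, n)
        y_pred = rng.integers(0, 9, n)
        cm = confusion_matrix(y_true, y_pred)
        rep = compute_metrics(cm)
        acc, mf1 = brute_force_metrics(y_true, y_pred)
        assert np.isclose(rep.accuracy, acc)
        assert np.isclose(rep.macro_f1, mf1)
        assert cm.sum() == n  # conservation


def test_diagonal_confusion_matrix_is_perfect():
    cm = np.diag([5, 3, 7, 2, 9, 4, 6, 1, 8])
    rep = compute_metrics(cm)
    assert rep.accuracy == 1.0
    assert rep.macro_f1 == 1.0


def test_two_class_toy_counts_match_hand_computation():
    # TP=8, FP=2, FN=2, TN=8 for class 0 in a 2-class problem
    cm = np.zeros((9, 9), dtype=int)
    cm[0, 0] = 8
    cm[0, 1] = 2
    cm[1, 0] = 2
    cm[1, 1] = 8
    rep = compute_metrics(cm)
    assert np.isclose(rep.precision[0], 0.8)
    assert np.isclose(rep.recall[0], 0.8)
    assert np.isclose(rep.f1[0], 0.8)
    assert np.isclose(rep.accuracy, 0.8)


def test_absent_class_has_zero_f1_by_convention():
    cm = np.zeros((9, 9), dtype=int)
    cm[0, 0] = 10
    cm[1, 1] = 10
    rep = compute_metrics(cm)
    assert rep.f1[5] == 0.0
    assert rep.accuracy == 1.0


def test_micro_accuracy_equals_trace_over_total_on_random_matrices():
    rng = np.random.default_rng(1)
    for _ in range(20):
        cm = rng.integers(0, 30, (9, 9))
        rep = compute_metrics(cm)
        tp = np.diag(cm).sum()
        tn = np.array([cm.sum() - cm[c].sum() - cm[:, c].sum() + cm[c, c] for c in range(9)])
        fp = cm.sum(axis=0) - np.diag(cm)
        fn = cm.sum(axis=1) - np.diag(cm)
        # one-vs-rest micro accuracy reduces to trace/total in multiclass
        micro = tp / cm.sum()
        assert np.isclose(rep.accuracy, micro)
        assert np.all(tp + tn + fp.sum() >= 0)  # counts consistent


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        compute_metrics(np.zeros((9, 9), dtype=int))


def test_evaluate_under_conditions_reports_and_errors():
    preds = lambda X: np.zeros(len(X), dtype=int)
    ds = {"none": (np.zeros((4, 3)), np.array([0, 0, 1, 2]))}
    out = evaluate_under_conditions(preds, ds, model_name="knn")
    rep, cm = out["none"]
    assert rep.n == 4
    assert cm[0, 0] == 2
    with pytest.raises(KeyError):
        evaluate_under_conditions(preds, {"contact": None})


# --- Friedman ----------------------------------------------------------------


def test_friedman_identical_models_gives_zero_statistic():
    A = np.tile([[0.9, 0.9, 0.9]], (4, 1))
    stat, p = friedman_test(A)
    assert stat == 0.0
    assert p == 1.0


def test_friedman_matches_direct_rank_formula_on_hand_blocks():
    # 3 models, 4 blocks, no ties; ranks fixed by construction
    A = np.array(
        [[0.9, 0.8, 0.7], [0.85, 0.8, 0.75], [0.95, 0.9, 0.6], [0.7, 0.65, 0.6]]
    )
    n, k = A.shape
    ranks = np.array([[3, 2, 1]] * 4)  # higher accuracy -> higher rank
    R = ranks.sum(axis=0)
    expected = 12.0 / (n * k * (k + 1)) * (R**2).sum() - 3 * n * (k + 1)
    stat, p = friedman_test(A)
    assert np.isclose(stat, expected)
    s2, p2 = stats.friedmanchisquare(*A.T)
    assert np.isclose(stat, s2)
    assert np.isclose(p, p2)


def test_friedman_agrees_with_scipy_under_ties():
    rng = np.random.default_rng(2)
    A = np.round(rng.uniform(0.5, 1.0, (8, 4)), 1)  # rounding forces ties
    stat, p = friedman_test(A)
    s2, p2 = stats.friedmanchisquare(*A.T)
    assert np.isclose(stat, s2)
    assert np.isclose(p, p2)


def test_friedman_two_model_strict_dominance_reaches_design_minimum_p():
    for n in (3, 5):
        A = np.column_stack([np.full(n, 0.9), np.full(n, 0.7)])
        stat, p = friedman_test(A)
        assert np.isclose(stat, n)  # all blocks rank identically
        assert np.isclose(p, stats.chi2.sf(n, 1))


def test_friedman_input_validation():
    with pytest.raises(ValueError):
        friedman_test(np.ones((3,)))
    with pytest.raises(ValueError):
        friedman_test(np.ones((1, 3)))


# --- UMAP plumbing -----------------------------------------------------------


def test_umap_projection_shape_and_cluster_structure():
    from sklearn.metrics import silhouette_score

    from eitgest.evaluation import umap_projection

    rng = np.random.default_rng(3)
    centers = rng.normal(scale=8.0, size=(4, 10))
    X = np.concatenate([c + rng.normal(size=(30, 10)) for c in centers])
    labels = np.repeat(np.arange(4), 30)
    coords = umap_projection(X, labels, seed=0)
    assert coords.shape == (120, 2)
    assert silhouette_score(coords, labels) > 0
    with pytest.raises(ValueError):
        umap_projection(X[:10], labels[:10])


def test_nearest_centroid_regions_cover_grid():
    rng = np.random.default_rng(4)
    coords = rng.normal(size=(60, 2))
    labels = np.repeat(np.arange(3), 20)
    xs, ys, region = nearest_centroid_regions(coords, labels, grid_n=40)
    assert region.shape == (40, 40)
    assert set(np.unique(region)) <= {0, 1, 2}
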