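import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painswarm.metrics import (
    SampleSizeSpec,
    classification_metrics,
    confusion_matrix,
    correlation_report,
    roc_auc,
    sample_size,
)


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------
def test_confusion_exhaustive_count():
    cm = confusion_matrix([0, 1, 1, 0], [0, 1, 0, 0])
    assert cm.tolist() == [[2, 0], [1, 1]]


def test_confusion_identity_and_degenerate():
    y = [0, 1, 0, 1, 1]
    assert np.trace(confusion_matrix(y, y)) == 5
    cm = confusion_matrix(y, [0] * 5)
    assert cm[:, 1].sum() == 0  # nothing predicted positive


def test_confusion_validation():
    with pytest.raises(ValueError, match="mismatch"):
        confusion_matrix([0, 1], [0])
    with pytest.raises(ValueError, match="0/1"):
        confusion_matrix([0, 2], [0, 1])


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------
def _oracle_metrics(cm):
    """Scalar-loop macro metrics, zero-division as 0."""
    per_class = []
    for c in (0, 1):
        tp = cm[c][c]
        col = cm[0][c] + cm[1][c]
        row = cm[c][0] + cm[c][1]
        prec = tp / col if col else 0.0
        rec = tp / row if row else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class.append((prec, rec, f1))
    n = sum(sum(r) for r in cm)
    return {
        "accuracy": (cm[0][0] + cm[1][1]) / n,
        "precision_macro": (per_class[0][0] + per_class[1][0]) / 2,
        "recall_macro": (per_class[0][1] + per_class[1][1]) / 2,
        "f1_macro": (per_class[0][2] + per_class[1][2]) / 2,
    }


def test_metrics_hand_example():
    out = classification_metrics(np.array([[6, 1], [1, 2]]))
    assert out["accuracy"] == pytest.approx(0.8)
    # class 1: precision 2/3, recall 2/3; class 0: 6/7 both
    assert out["precision_macro"] == pytest.approx((6 / 7 + 2 / 3) / 2)
    assert out["recall_macro"] == pytest.approx((6 / 7 + 2 / 3) / 2)


def test_metrics_perfect_and_empty():
    perfect = classification_metrics(np.array([[5, 0], [0, 5]]))
    assert all(v == 1.0 for v in perfect.values())
    with pytest.raises(ValueError):
        classification_metrics(np.zeros((2, 2), dtype=int))


def test_metrics_absent_class_zero_filled():
    # class 1 never occurs nor is predicted: its P/R/F1 count as 0
    with pytest.warns(UserWarning, match="0/0"):
        out = classification_metrics(np.array([[8, 0], [0, 0]]))
    assert out["accuracy"] == 1.0
    assert out["precision_macro"] == pytest.approx(0.5)
    assert out["recall_macro"] == pytest.approx(0.5)


def test_metrics_match_oracle_on_random_matrices():
    rng = np.random.default_rng(10)
    import warnings

    for _ in range(200):
        cm = rng.integers(0, 20, size=(2, 2))
        if cm.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = classification_metrics(cm)
        want = _oracle_metrics(cm.tolist())
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-10), key


def test_metrics_agree_with_sklearn_when_defined():
    from sklearn.metrics import precision_score, recall_score

    rng = np.random.default_rng(11)
    y_true = rng.integers(0, 2, size=60)
    y_pred = rng.integers(0, 2, size=60)
    out = classification_metrics(confusion_matrix(y_true, y_pred))
    assert out["precision_macro"] == pytest.approx(
        precision_score(y_true, y_pred, average="macro", zero_division=0)
    )
    assert out["recall_macro"] == pytest.approx(
        recall_score(y_true, y_pred, average="macro", zero_division=0)
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------
def _oracle_auc(y, s):
    """All positive-negative pairs; ties count one half."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    auc, _ = roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2])
    assert auc == pytest.approx(0.75)
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])[0] == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])[0] == 0.5


def test_auc_single_class_error():
    with pytest.raises(ValueError, match="class 1"):
        roc_auc([0, 0, 0], [0.1, 0.2, 0.3])


def test_auc_matches_pair_oracle_on_random_instances():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = int(rng.integers(4, 50))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        got, _ = roc_auc(y, s)
        assert got == pytest.approx(_oracle_auc(y, s), abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=30)
    if y.min() == y.max():
        return
    s = rng.normal(size=30)
    base, _ = roc_auc(y, s)
    warped, _ = roc_auc(y, np.exp(2.0 * s) + 1.0)
    assert warped == pytest.approx(base, abs=1e-12)


def test_roc_points_shape_and_monotonicity():
    rng = np.random.default_rng(13)
    y = rng.integers(0, 2, size=40)
    s = np.round(rng.uniform(size=40), 1)
    _, points = roc_auc(y, s)
    assert points[0] == (0.0, 0.0)
    assert points[-1] == (1.0, 1.0)
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    assert fpr == sorted(fpr)
    assert tpr == sorted(tpr)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(14)
    y = rng.integers(0, 2, size=100)
    s = rng.uniform(size=100)
    assert roc_auc(y, s)[0] == pytest.approx(roc_auc_score(y, s), abs=1e-12)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------
def test_correlation_definitions():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    frame = pd.DataFrame({"x": x, "neg": -x, "perm": [1.0, 3.0, 2.0, 4.0]})
    corr = correlation_report(frame)
    assert corr.loc["x", "x"] == pytest.approx(1.0)
    assert corr.loc["x", "neg"] == pytest.approx(-1.0)
    assert corr.loc["x", "perm"] == pytest.approx(0.8)
    assert np.allclose(corr, corr.T)
    assert (corr.abs().to_numpy() <= 1 + 1e-12).all()


def test_correlation_pairs_and_constant_columns():
    frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": 1.0})
    with pytest.warns(UserWarning, match="constant"):
        pairs = correlation_report(frame, pairs=[("a", "b"), ("a", "c")])
    assert pairs.loc[0, "pearson_r"] == pytest.approx(1.0)
    assert np.isnan(pairs.loc[1, "pearson_r"])


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "z,p,d,expected",
    [
        (1.96, 0.65, 0.05, 350),
        (1.96, 0.50, 0.05, 385),
        (1.96, 1e-9, 0.05, 1),
    ],
)
def test_sample_size_values(z, p, d, expected):
    assert sample_size(SampleSizeSpec(z=z, p=p, d=d)) == expected


def test_sample_size_validation():
    with pytest.raises(ValueError):
        SampleSizeSpec(p=0.0)
    with pytest.raises(ValueError):
        SampleSizeSpec(p=1.2)
    with pytest.raises(ValueError):
        SampleSizeSpec(d=0.0)
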