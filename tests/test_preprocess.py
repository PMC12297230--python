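import numpy as np
import pytest

from painswarm.cohort import CohortTable
from painswarm.preprocess import (
    PipelineConfig,
    SplitError,
    impute_missing,
    make_xy,
    preprocess_region,
    smote_oversample,
    split_train_test,
    standardize,
)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------
def _with_missing(frame):
    frame = frame.copy()
    frame.loc[1, "exercising_hours_day"] = np.nan
    return CohortTable(frame)


def test_impute_zero_fills_and_keeps_rows(toy_frame):
    table = _with_missing(toy_frame)
    out = impute_missing(table, "zero")
    assert out.n_rows == 3
    assert out.frame.loc[1, "exercising_hours_day"] == 0


def test_impute_drop_row_removes_incomplete(toy_frame):
    table = _with_missing(toy_frame)
    out = impute_missing(table, "drop_row")
    assert out.n_rows == 2


def test_impute_identity_on_complete_table(toy_frame):
    table = CohortTable(toy_frame)
    for policy in ("zero", "drop_row"):
        assert impute_missing(table, policy) is table
    with pytest.raises(ValueError):
        impute_missing(table, "interpolate")


# ---------------------------------------------------------------------------
# make_xy
# ---------------------------------------------------------------------------
def test_make_xy_excludes_identifier_and_pain_columns(small_cohort):
    X, y, names = make_xy(small_cohort, "neck_pain_current")
    assert "name" not in names
    assert not any("_pain_" in n for n in names)
    assert X.shape == (small_cohort.n_rows, len(names))
    assert set(np.unique(y)) <= {0, 1}


def test_make_xy_fidelity_flag_keeps_same_region_outcomes(small_cohort):
    _, _, names = make_xy(
        small_cohort, "neck_pain_current", include_same_region_outcomes=True
    )
    assert "neck_pain_impairment" in names
    assert "neck_pain_last7" in names
    assert "knee_pain_current" not in names


def test_make_xy_rejects_non_binary_target(toy_frame):
    frame = toy_frame.copy()
    frame["extra_target"] = [0, 1, 2]
    table = CohortTable(frame, validated=True)
    with pytest.raises(ValueError, match="binary"):
        make_xy(table, "extra_target")


def test_make_xy_label_length_matches_rows(medium_cohort):
    _, y, _ = make_xy(medium_cohort, "low_back_pain_current")
    assert len(y) == 350


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------
def test_split_counts_350_gives_280_70(medium_cohort):
    X, y, names = make_xy(medium_cohort, "low_back_pain_current")
    bundle = split_train_test(X, y, 0.20, seed=42, feature_names=names)
    assert len(bundle.y_train) == 280
    assert len(bundle.y_test) == 70


def test_split_deterministic_and_complementary(medium_cohort):
    X, y, _ = make_xy(medium_cohort, "neck_pain_current")
    b1 = split_train_test(X, y, 0.20, seed=7)
    b2 = split_train_test(X, y, 0.20, seed=7)
    assert np.array_equal(b1.test_index, b2.test_index)
    swapped = split_train_test(X, y, 0.80, seed=7)
    # 0.2 vs 0.8 fractions partition into complementary-size index sets
    assert len(swapped.test_index) == len(b1.train_index)
    union = set(b1.train_index) | set(b1.test_index)
    assert union == set(range(len(y)))


def test_split_stratification_small_balanced():
    X = np.arange(20, dtype=float).reshape(10, 2)
    y = np.array([0, 1] * 5)
    bundle = split_train_test(X, y, 0.2, seed=0)
    assert (bundle.y_test == 0).sum() == 1
    assert (bundle.y_test == 1).sum() == 1


def test_split_errors():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError):
        split_train_test(X, np.zeros(10, dtype=int), 1.5)
    with pytest.raises(SplitError):
        split_train_test(X, np.array([0] * 9 + [1]), 0.2, seed=0)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------
def _segment_membership(s, minority, atol=1e-9):
    """Brute force: is s on a segment between two minority rows?"""
    for i in range(len(minority)):
        for j in range(len(minority)):
            if i == j:
                continue
            a, b = minority[i], minority[j]
            diff = b - a
            live = np.abs(diff) > atol
            if not live.any():
                if np.allclose(s, a, atol=atol):
                    return True
                continue
            u = (s[live] - a[live]) / diff[live]
            if np.allclose(u, u[0], atol=1e-7) and -1e-9 <= u[0] <= 1 + 1e-9:
                if np.allclose(a + u[0] * diff, s, atol=1e-7):
                    return True
    return False


def test_smote_balances_counts():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(100, 4))
    y = np.array([0] * 90 + [1] * 10)
    Xr, yr = smote_oversample(X, y, k_neighbors=5, seed=1)
    assert (yr == 0).sum() == (yr == 1).sum() == 90
    # originals preserved verbatim, in order
    assert np.array_equal(Xr[:100], X)


def test_smote_synthetic_rows_are_convex_combinations():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 3))
    y = np.array([0] * 24 + [1] * 6)
    Xr, yr = smote_oversample(X, y, k_neighbors=3, seed=2)
    minority = X[y == 1]
    synth = Xr[30:]
    assert len(synth) == 18
    for s in synth:
        assert _segment_membership(s, minority)


def test_smote_balanced_input_unchanged():
    X = np.arange(12, dtype=float).reshape(6, 2)
    y = np.array([0, 0, 0, 1, 1, 1])
    Xr, yr = smote_oversample(X, y, seed=0)
    assert Xr is X and yr is y


def test_smote_single_minority_sample_duplicates():
    X = np.vstack([np.zeros((5, 2)), np.ones((1, 2))])
    y = np.array([0] * 5 + [1])
    with pytest.warns(UserWarning, match="duplication"):
        Xr, yr = smote_oversample(X, y, seed=0)
    assert (yr == 1).sum() == 5
    assert np.allclose(Xr[6:], 1.0)


def test_smote_requires_two_classes():
    with pytest.raises(ValueError):
        smote_oversample(np.zeros((4, 2)), np.zeros(4, dtype=int))


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------
def test_standardize_definition_and_inverse():
    rng = np.random.default_rng(1)
    X = rng.normal(5, 3, size=(40, 3))
    Xt = rng.normal(5, 3, size=(10, 3))
    from painswarm.preprocess import SplitBundle

    bundle = SplitBundle(
        X_train=X.copy(), X_test=Xt.copy(),
        y_train=np.zeros(40, int), y_test=np.zeros(10, int),
        feature_names=["a", "b", "c"], split_seed=0,
    )
    out = standardize(bundle)
    assert np.allclose(out.X_train.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(out.X_train.std(axis=0), 1, atol=1e-9)
    recovered = out.X_train * out.scaler_sd + out.scaler_mean
    assert np.allclose(recovered, X, atol=1e-9)
    # a test value equal to the training mean maps to 0
    probe = (bundle.scaler_mean - out.scaler_mean) / out.scaler_sd
    assert np.allclose(probe, 0)


def test_standardize_constant_column_goes_to_zero():
    from painswarm.preprocess import SplitBundle

    X = np.column_stack([np.full(5, 7.0), np.arange(5, dtype=float)])
    bundle = SplitBundle(
        X_train=X, X_test=X.copy(),
        y_train=np.zeros(5, int), y_test=np.zeros(5, int),
        feature_names=["const", "ramp"], split_seed=0,
    )
    with pytest.warns(UserWarning, match="constant"):
        out = standardize(bundle)
    assert np.allclose(out.X_train[:, 0], 0)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------
def test_pipeline_order_and_test_fold_untouched(medium_cohort):
    cfg = PipelineConfig(split_seed=42)
    bundle = preprocess_region(medium_cohort, "low_back", cfg)
    classes, counts = np.unique(bundle.y_train, return_counts=True)
    assert counts[0] == counts[1]  # SMOTE parity
    assert np.allclose(bundle.X_train.mean(axis=0), 0, atol=1e-9)
    # test rows are original records: invert scaling and match source rows
    X, y, names = make_xy(
        impute_missing(medium_cohort, "zero"), "low_back_pain_current"
    )
    raw_test = bundle.X_test * bundle.scaler_sd + bundle.scaler_mean
    assert np.allclose(raw_test, X[bundle.test_index], atol=1e-8)
    assert np.array_equal(bundle.y_test, y[bundle.test_index])


def test_bundle_save_writes_matrices_and_sidecar(tmp_path, medium_cohort):
    bundle = preprocess_region(medium_cohort, "neck")
    bundle.save(tmp_path / "bundle")
    import json

    sidecar = json.loads((tmp_path / "bundle" / "bundle.json").read_text())
    assert sidecar["split_seed"] == 42
    assert sidecar["smote_applied"] is True
    counts = sidecar["class_counts_train"]
    assert counts["0"] == counts["1"]
    assert (tmp_path / "bundle" / "X_train.csv").exists()
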