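"""Preprocessing chain: impute -> features/labels -> split -> SMOTE -> z-score.

The order is fixed by the study design: the identifier column is dropped and
the target cast to integer, the data are split 80/20 (stratified, seeded),
the minority class of the *training fold only* is oversampled with SMOTE to
parity, and features are standardised with a scaler fitted on the resampled
training matrix. The test fold always contains original records only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .cohort import ID_COLUMN, CohortTable, pain_column, pain_columns


class SplitError(ValueError):
    """Raised when a stratified split cannot place both classes in both folds."""


@dataclass
class PipelineConfig:
    """Knobs of the preprocessing chain.

    test_fraction : held-out fraction of rows (default 0.20).
    split_seed : random state of the stratified split (study value 42).
    smote_k : SMOTE neighbour count; reduced automatically when the minority
        class has fewer than k+1 members.
    include_same_region_outcomes : leakage flag — when True the target
        region's impairment/last-7-days columns stay in the feature set
        (near-proxies of the label; off by default).
    scale_before_smote : fit the scaler on the pre-SMOTE training fold
        instead of the resampled one.
    missing_policy : ``zero`` (blanks read as 0) or ``drop_row``.
    """

    test_fraction: float = 0.20
    split_seed: int = 42
    smote_seed: int = 0
    smote_k: int = 5
    include_same_region_outcomes: bool = False
    scale_before_smote: bool = False
    missing_policy: str = "zero"
    stratify: bool = True


@dataclass
class SplitBundle:
    """Train/test matrices plus fitted scaling parameters."""

    X_train: np.ndarray
    X_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    feature_names: list[str]
    split_seed: int
    smote_applied: bool = False
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None

    def save(self, directory: str | Path) -> None:
        """Write matrices as CSV plus a JSON sidecar of seeds and scaling."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("X_train", "X_test"):
            pd.DataFrame(getattr(self, name), columns=self.feature_names).to_csv(
                directory / f"{name}.csv", index=False
            )
        for name in ("y_train", "y_test"):
            pd.Series(getattr(self, name), name="label").to_csv(
                directory / f"{name}.csv", index=False
            )
        sidecar = {
            "split_seed": int(self.split_seed),
            "smote_applied": bool(self.smote_applied),
            "feature_names": self.feature_names,
            "scaler_mean": None
            if self.scaler_mean is None
            else [float(v) for v in self.scaler_mean],
            "scaler_sd": None
            if self.scaler_sd is None
            else [float(v) for v in self.scaler_sd],
            "class_counts_train": {
                str(k): int(v)
                for k, v in zip(*np.unique(self.y_train, return_counts=True))
            },
            "class_counts_test": {
                str(k): int(v)
                for k, v in zip(*np.unique(self.y_test, return_counts=True))
            },
        }
        (directory / "bundle.json").write_text(json.dumps(sidecar, indent=2))


def impute_missing(table: CohortTable, policy: str = "zero") -> CohortTable:
    """Resolve missing numeric cells.

    ``zero`` replaces blanks with 0 (the study's convention for
    missing/incomplete entries); ``drop_row`` removes any incomplete row.
    """
    if policy not in ("zero", "drop_row"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    df = table.frame
    numeric = [c for c in df.columns if c != ID_COLUMN]
    if not df[numeric].isna().any().any():
        return table
    df = df.copy()
    if policy == "zero":
        df[numeric] = df[numeric].fillna(0)
    else:
        df = df.dropna(subset=numeric).reset_index(drop=True)
    return CohortTable(df, validated=True)


def make_xy(
    table: CohortTable,
    target_column: str,
    include_same_region_outcomes: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the feature matrix and binary label vector for one pain outcome.

    The identifier column, the target itself and — by default — every other
    pain column are excluded from the features: same-region impairment and
    last-7-days outcomes are near-deterministic proxies of the label, and
    other regions' outcomes are labels of sibling tasks.
    """
    df = table.frame
    if target_column not in df.columns:
        raise KeyError(f"target column {target_column!r} not in table")
    y = df[target_column].to_numpy()
    if np.isnan(y).any():
        raise ValueError(f"target column {target_column!r} has missing values")
    y = y.astype(int)
    bad = set(np.unique(y)) - {0, 1}
    if bad:
        raise ValueError(
            f"target column {target_column!r} is not binary after integer cast: "
            f"unexpected values {sorted(bad)}"
        )
    drop = {ID_COLUMN, target_column}
    excluded = set(pain_columns())
    if include_same_region_outcomes:
        region = target_column.rsplit("_pain_", 1)[0]
        excluded -= {pain_column(region, s) for s in ("pain_impairment", "pain_last7")}
    drop |= excluded
    feature_names = [c for c in df.columns if c not in drop]
    X = df[feature_names].to_numpy(dtype=float)
    return X, y, feature_names


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.20,
    seed: int = 42,
    stratify: bool = True,
    feature_names: list[str] | None = None,
) -> SplitBundle:
    """Seeded (optionally stratified) row partition; fractions within one row."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    idx = np.arange(len(y))
    strat = y if stratify else None
    try:
        tr, te = _sk_split(
            idx, test_size=test_fraction, random_state=seed, stratify=strat
        )
    except ValueError as exc:
        raise SplitError(str(exc)) from exc
    if stratify:
        for fold, name in ((tr, "train"), (te, "test")):
            if len(np.unique(y[fold])) < 2:
                raise SplitError(f"a class is absent from the {name} fold")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return SplitBundle(
        X_train=X[tr],
        X_test=X[te],
        y_train=y[tr],
        y_test=y[te],
        feature_names=list(feature_names),
        split_seed=seed,
        train_index=np.asarray(tr),
        test_index=np.asarray(te),
    )


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling to exact class parity.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``, where
    ``x`` is a minority row and ``x_nn`` one of its k nearest minority
    neighbours (Euclidean). Original rows are preserved verbatim; already
    balanced input is returned unchanged. A minority class of a single
    sample is duplicated (no neighbours to interpolate).
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE needs exactly 2 classes, found {len(classes)}")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    rng = np.random.default_rng(seed)
    if len(X_min) == 1:
        warnings.warn(
            "minority class has a single sample; SMOTE falls back to duplication",
            stacklevel=2,
        )
        synth = np.repeat(X_min, n_needed, axis=0)
    else:
        k = min(k_neighbors, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, len(X_min), size=n_needed)
        pick = rng.integers(1, k + 1, size=n_needed)
        u = rng.uniform(0.0, 1.0, size=n_needed)
        x0 = X_min[base]
        x1 = X_min[neigh[base, pick]]
        synth = x0 + u[:, None] * (x1 - x0)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def standardize(bundle: SplitBundle) -> SplitBundle:
    """Fit a z-score scaler on the training matrix; transform both folds.

    Constant training columns (sd = 0) map to all zeros (divide-by-one
    convention) with a warning.
    """
    if bundle.X_train.size == 0:
        raise ValueError("cannot standardize an empty training matrix")
    scaler = StandardScaler().fit(bundle.X_train)
    sd = np.sqrt(scaler.var_)
    if np.any(sd == 0):
        flat = [bundle.feature_names[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(
            f"constant training columns standardised to zero: {flat}", stacklevel=2
        )
    bundle.X_train = scaler.transform(bundle.X_train)
    bundle.X_test = scaler.transform(bundle.X_test)
    bundle.scaler_mean = scaler.mean_.copy()
    # sklearn's divide-by-one convention for zero-variance columns
    bundle.scaler_sd = np.where(sd == 0, 1.0, sd)
    return bundle


def preprocess_region(
    table: CohortTable,
    region: str,
    cfg: PipelineConfig | None = None,
) -> SplitBundle:
    """Full chain for one region's current-pain outcome.

    impute -> make_xy -> stratified split -> SMOTE (train only) -> z-score.
    """
    cfg = cfg or PipelineConfig()
    table = impute_missing(table, cfg.missing_policy)
    target = pain_column(region, "pain_current")
    X, y, names = make_xy(table, target, cfg.include_same_region_outcomes)
    bundle = split_train_test(
        X,
        y,
        test_fraction=cfg.test_fraction,
        seed=cfg.split_seed,
        stratify=cfg.stratify,
        feature_names=names,
    )
    if cfg.scale_before_smote:
        bundle = standardize(bundle)
    Xr, yr = smote_oversample(
        bundle.X_train, bundle.y_train, k_neighbors=cfg.smote_k, seed=cfg.smote_seed
    )
    bundle.smote_applied = len(yr) != len(bundle.y_train)
    bundle.X_train, bundle.y_train = Xr, yr
    if not cfg.scale_before_smote:
        bundle = standardize(bundle)
    return bundle
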