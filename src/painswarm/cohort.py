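"""Cohort table schema, validation and CSV input/output.

One row per participant: demographic / work / physical / lifestyle predictors
plus, for each of nine anatomical regions, three binary pain outcomes
(current pain, activity-preventing pain, pain within the last 7 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: Anatomical regions assessed by the questionnaire, in report order.
REGIONS: tuple[str, ...] = (
    "neck",
    "shoulder",
    "elbow",
    "wrist",
    "thoracic",
    "low_back",
    "hip",
    "knee",
    "ankle",
)

#: Pain outcome suffixes: current presence, functional impairment, last-7-days.
PAIN_SUFFIXES: tuple[str, ...] = ("pain_current", "pain_impairment", "pain_last7")

#: Numeric predictor columns in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "age",
    "sex",
    "scientific_rank",
    "experience_years",
    "working_hours_day",
    "work_days_week",
    "college",
    "weight_kg",
    "height_cm",
    "bmi",
    "extra_work",
    "exercise",
    "exercising_days_week",
    "exercising_hours_day",
)

#: Optional identifier column, dropped before modelling.
ID_COLUMN = "name"

BINARY_FEATURES = ("sex", "extra_work", "exercise")
ORDINAL_FEATURES = {"scientific_rank": (1, 5), "college": (1, 5)}


def pain_columns() -> list[str]:
    """All 27 pain outcome column names, region-major."""
    return [f"{r}_{s}" for r in REGIONS for s in PAIN_SUFFIXES]


def pain_column(region: str, suffix: str = "pain_current") -> str:
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if suffix not in PAIN_SUFFIXES:
        raise ValueError(f"unknown pain outcome {suffix!r}")
    return f"{region}_{suffix}"


class SchemaError(ValueError):
    """Raised when a cohort table does not satisfy the expected schema."""


@dataclass
class CohortTable:
    """Validated participant table.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per participant. Must contain every feature and pain column;
        an optional ``name`` identifier column is allowed. Missing numeric
        cells are held as NaN until an imputation policy is applied.
    """

    frame: pd.DataFrame
    validated: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.validated:
            self.validate()
            self.validated = True

    # -- schema ------------------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return list(FEATURE_COLUMNS)

    @property
    def pain_columns(self) -> list[str]:
        return pain_columns()

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        df = self.frame
        if len(df) < 1:
            raise SchemaError("cohort table has no rows")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate column names: {dupes}")
        required = list(FEATURE_COLUMNS) + pain_columns()
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        # binary domains ({0,1}; NaN allowed pending imputation)
        for col in list(BINARY_FEATURES) + pain_columns():
            vals = df[col].dropna().unique()
            bad = [v for v in vals if v not in (0, 1)]
            if bad:
                raise SchemaError(f"column {col!r} must be binary 0/1, found {bad}")
        for col, (lo, hi) in ORDINAL_FEATURES.items():
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise SchemaError(f"column {col!r} must lie in [{lo}, {hi}]")
        self._check_bmi_identity()

    def _check_bmi_identity(self, tol: float = 0.5) -> None:
        # BMI = kg / m^2; generous tolerance for rounded source values
        df = self.frame
        sub = df[["weight_kg", "height_cm", "bmi"]].dropna()
        if sub.empty:
            return
        implied = sub["weight_kg"] / (sub["height_cm"] / 100.0) ** 2
        off = (implied - sub["bmi"]).abs()
        if (off > tol).any():
            worst = float(off.max())
            raise SchemaError(
                f"bmi inconsistent with weight/height (max deviation {worst:.2f} "
                f"> {tol} kg/m^2)"
            )

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _normalize_header(name: str) -> str:
    """Lowercase, trim and underscore a CSV header."""
    out = name.strip().lower()
    for ch in (" ", "-", "/"):
        out = out.replace(ch, "_")
    while "__" in out:
        out = out.replace("__", "_")
    return out


def load_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> CohortTable:
    """Read a cohort CSV (comma-separated, header row, UTF-8).

    Headers are normalised (lowercased, spaces/slashes to underscores);
    ``column_map`` (dict or YAML file of ``source: canonical`` pairs) renames
    nonstandard headers afterwards. Unparseable numeric cells become NaN and
    are resolved later by :func:`painswarm.preprocess.impute_missing`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=",", encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    if len(df) == 0:
        raise SchemaError(f"input file has a header but no rows: {path}")
    df.columns = [_normalize_header(c) for c in df.columns]
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh) or {}
        df = df.rename(columns={_normalize_header(k): v for k, v in column_map.items()})
    numeric = [c for c in df.columns if c != ID_COLUMN]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return CohortTable(df)


def n_missing(table: CohortTable) -> int:
    """Count missing numeric cells (identifier column excluded)."""
    cols = [c for c in table.frame.columns if c != ID_COLUMN]
    return int(table.frame[cols].isna().sum().sum())


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.to_csv(path)


def _as_feature_frame(frame: pd.DataFrame, columns: Iterable[str]) -> np.ndarray:
    return frame[list(columns)].to_numpy(dtype=float)
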