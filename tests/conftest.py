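import numpy as np
import pandas as pd
import pytest

from painswarm.cohort import FEATURE_COLUMNS, REGIONS, CohortTable, pain_columns
from painswarm.simulate import CohortSpec, generate_cohort


def make_toy_frame(n_rows: int = 3, seed: int = 0) -> pd.DataFrame:
    """Small schema-complete frame with hand-checkable values."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rows):
        height = 160.0 + 5 * i
        weight = 60.0 + 8 * i
        row = {
            "name": f"p{i}",
            "age": 30 + i,
            "sex": i % 2,
            "scientific_rank": 1 + (i % 5),
            "experience_years": 5 + i,
            "working_hours_day": 8.0,
            "work_days_week": 5,
            "college": 1 + (i % 5),
            "weight_kg": weight,
            "height_cm": height,
            "bmi": round(weight / (height / 100) ** 2, 2),
            "extra_work": 1,
            "exercise": i % 2,
            "exercising_days_week": 2,
            "exercising_hours_day": 1.0,
        }
        for col in pain_columns():
            row[col] = int(rng.integers(0, 2))
        # enforce structural plausibility: impairment/last7 <= current
        for r in REGIONS:
            cur = row[f"{r}_pain_current"]
            row[f"{r}_pain_impairment"] = min(row[f"{r}_pain_impairment"], cur)
            row[f"{r}_pain_last7"] = min(row[f"{r}_pain_last7"], cur)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    return make_toy_frame()


@pytest.fixture
def toy_csv(tmp_path, toy_frame):
    path = tmp_path / "toy.csv"
    toy_frame.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """An 80-row synthetic cohort shared by pipeline-level tests."""
    return generate_cohort(CohortSpec(n=80, seed=12))


@pytest.fixture(scope="session")
def medium_cohort() -> CohortTable:
    return generate_cohort(CohortSpec(n=350, seed=5))
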