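import numpy as np
import pandas as pd
import pytest

from daptsurv import Cohort, FeatureSchema, TimeGrid


@pytest.fixture
def schema() -> FeatureSchema:
    return FeatureSchema(
        categorical={
            "sex": ("F", "M"),
            "diabetes": ("0", "1"),
            "ethnicity": ("hispanic", "nhb", "nhw", "other"),
        },
        numeric={"age": (60.0, 12.0)},
    )


@pytest.fixture
def grid() -> TimeGrid:
    return TimeGrid()


def make_cohort(schema: FeatureSchema, n: int, seed: int = 0,
                endpoint: str = "ischemic") -> Cohort:
    """Random cohort that validates against the 4-feature test schema."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "sex": rng.choice(["F", "M"], size=n),
        "diabetes": rng.choice(["0", "1"], size=n).astype(str),
        "ethnicity": rng.choice(["hispanic", "nhb", "nhw", "other"], size=n),
        "age": rng.normal(60, 12, size=n),
        "time_days": rng.uniform(9.0, 365.0, size=n),
        "event": rng.integers(0, 2, size=n),
    })
    return Cohort(schema=schema, frame=frame, endpoint_name=endpoint)


@pytest.fixture
def cohort(schema) -> Cohort:
    return make_cohort(schema, 40, seed=3)
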