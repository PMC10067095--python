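import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from evsubtype.io import AbundanceMatrix

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    """3 proteins x 4 samples with one missing cell."""
    df = pd.DataFrame(
        {
            "s1": [4.0, 100.0, 7.0],
            "s2": [8.0, 200.0, 9.0],
            "s3": [np.nan, 150.0, 8.0],
            "s4": [6.0, 120.0, 10.0],
        },
        index=["pA", "pB", "pC"],
    )
    return AbundanceMatrix(df)


def make_annotations(rows: list[dict]) -> pd.DataFrame:
    """Build a validated-shape annotation frame from minimal dicts."""
    base = {
        "cohort": "cohort1",
        "group": "HC1",
        "age": 60,
        "sex": "F",
        "os_time": np.nan,
        "os_event": np.nan,
        "curative_resection": None,
        "eligible": True,
    }
    full = [{**base, **r} for r in rows]
    df = pd.DataFrame(full)
    return df.set_index("sample_id", drop=False)
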