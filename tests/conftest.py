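"""Shared fixtures: reference tables and small synthetic datasets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CONDITIONS = ("OV90", "OVCAR4", "OVCAR3", "OVCAR5", "OVCA432")

# Published normalized mean counts of the nine-candidate screen (columns
# in mu1..mu5 order); used as a gate oracle fixture.
CANDIDATE_MEANS = {
    "AMH": (3.72, 4.73, 11.70, 15.95, 30.91),
    "CXCL11": (0.65, 1.06, 0.75, 3.36, 9.22),
    "EPGN": (0.00, 0.00, 0.21, 2.97, 34.75),
    "FAM3C": (3410.94, 5751.98, 4598.91, 7852.69, 10933.33),
    "GDNF": (0.00, 0.00, 0.16, 0.00, 47.86),
    "LIF": (87.28, 586.30, 616.71, 1515.45, 1895.35),
    "TGFA": (7.34, 586.50, 870.77, 1035.11, 5681.16),
    "TNFAIP2": (2222.38, 3571.95, 3406.09, 5590.16, 8712.42),
    "TNFSF12": (2.60, 0.56, 20.68, 27.71, 104.14),
}


@pytest.fixture(scope="session")
def candidate_means() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        CANDIDATE_MEANS, orient="index", columns=list(CONDITIONS)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    """3 genes x 4 samples (2 conditions x 2 replicates), all positive."""
    return pd.DataFrame(
        [[12, 15, 48, 52], [100, 90, 95, 110], [7, 9, 30, 2]],
        index=["g1", "g2", "g3"],
        columns=["A_r1", "A_r2", "B_r1", "B_r2"],
    )


@pytest.fixture()
def toy_condition_map() -> dict:
    return {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"}
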