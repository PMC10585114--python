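import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from msntools import MorphometryTable, Parcellation, make_parcellation

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def parc40() -> Parcellation:
    """Small two-hemisphere parcellation for fast unit tests."""
    return make_parcellation(40, 20, seed=11)


@pytest.fixture(scope="session")
def parc308() -> Parcellation:
    """Study-scale parcellation (308 regions, 152 left)."""
    return make_parcellation(308, 152, seed=0)


def make_table(values: np.ndarray, groups=None, attendance=None) -> MorphometryTable:
    """Wrap a raw (subjects x regions x 7) array in a MorphometryTable with
    simple alternating covariates."""
    n = values.shape[0]
    groups = groups if groups is not None else ["user", "control"] * (n // 2 + 1)
    rows = []
    for i in range(n):
        rows.append(
            {
                "subject_id": f"s{i:02d}",
                "group": groups[i],
                "age": 40.0 + 3 * i,
                "sex": "F" if i % 2 == 0 else "M",
                "tiv": 1.2e6 + 1e4 * i,
                "attendance": (attendance[i] if attendance is not None else np.nan),
            }
        )
    return MorphometryTable(values=values, subjects=pd.DataFrame(rows))


@pytest.fixture()
def tiny_table() -> MorphometryTable:
    """4 subjects x 6 regions x 7 features, reproducible random values."""
    rng = np.random.default_rng(5)
    return make_table(rng.normal(10.0, 2.0, size=(4, 6, 7)))
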