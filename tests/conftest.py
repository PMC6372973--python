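import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reprotrace.expression import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# master seed for all seeded simulations in the suite
SUITE_SEED = 20190110


@pytest.fixture(scope="session")
def suite_seed() -> int:
    return SUITE_SEED


def make_matrix(values: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    """Small handcrafted matrix; sample ids encode condition/day/replicate."""
    meta = []
    for sid in values:
        parts = sid.split("_")
        cond = parts[0]
        day = float(parts[1][1:]) if len(parts) == 3 else np.nan
        rep = int(parts[-1][1:])
        meta.append((sid, cond, day, rep))
    samples = pd.DataFrame(
        meta, columns=["sample", "condition", "day", "replicate"]
    ).set_index("sample")
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(vals, samples)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Two genes, two conditions at day 8 with 2 replicates each."""
    return make_matrix(
        {
            "highKLF4_d8_r1": [5.0, 3.0],
            "highKLF4_d8_r2": [5.0, 3.0],
            "lowKLF4_d8_r1": [4.0, 3.0],
            "lowKLF4_d8_r2": [4.0, 3.0],
        },
        genes=["GA", "GB"],
    )
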