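import numpy as np
import pandas as pd
import pytest

from mgpde import ExpressionMatrix, SimConfig, simulate_bulk
from mgpde.io import validate_sample_table

COVARIATES = ["sex", "age", "pmi", "rin", "batch"]


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.poisson(50, size=(20, 6)).astype(float)
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(20)], [f"s{i}" for i in range(6)], unit="counts"
    )


@pytest.fixture
def tiny_samples() -> pd.DataFrame:
    return validate_sample_table(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "group": ["case"] * 3 + ["control"] * 3,
                "sex": ["M", "F", "M", "F", "M", "F"],
                "age": [70, 75, 68, 72, 80, 66],
                "pmi": [10, 12, 8, 20, 15, 11],
                "rin": [6.0, 5.5, 7.0, 6.5, 4.0, 5.0],
                "batch": ["b1", "b2", "b1", "b2", "b1", "b2"],
            }
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at package defaults, shared across tests."""
    return simulate_bulk(SimConfig(seed=100))


@pytest.fixture(scope="session")
def null_cohort():
    """Global null: no composition shift, no regulatory effects."""
    return simulate_bulk(SimConfig(seed=101, composition_shift={}, n_regulatory_de=0))
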