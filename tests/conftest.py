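import numpy as np
import pandas as pd
import pytest

from sclc_caf import ExpressionMatrix, GeneSet, SimulationConfig, simulate_cohort


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 3 samples, linear scale, hand-checkable values."""
    df = pd.DataFrame(
        {"S1": [0.0, 2.0, 5.0, 1.0], "S2": [2.0, 4.0, 5.0, 3.0], "S3": [4.0, 6.0, 5.0, 8.0]},
        index=["A", "B", "C", "D"],
    )
    return ExpressionMatrix(df, scale="linear")


@pytest.fixture
def markers_ab() -> GeneSet:
    return GeneSet("markers", ("A", "B"))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort, shared across tests (read-only)."""
    return simulate_cohort(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A faster cohort for tests that only need the structure."""
    return simulate_cohort(SimulationConfig(n_samples=60, n_genes=800), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
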