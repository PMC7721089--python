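import numpy as np
import pandas as pd
import pytest

from m6ametab.io import ClinicalTable, ExpressionMatrix
from m6ametab.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller cohort for faster end-to-end style tests."""
    return simulate_cohort(SimulationConfig(n_samples=150, n_genes=600,
                                            n_metabolic_sets=20,
                                            category_pool_size=10, seed=5))


@pytest.fixture()
def toy_expression():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(6.0, 1.0, size=(10, 8)),
        index=[f"G{i}" for i in range(10)],
        columns=[f"S{i}" for i in range(8)],
    )
    return ExpressionMatrix(data)


@pytest.fixture()
def toy_clinical():
    rng = np.random.default_rng(1)
    n = 8
    return ClinicalTable(
        pd.DataFrame(
            {
                "os_time": rng.exponential(3.0, n),
                "os_event": rng.integers(0, 2, n),
                "age": rng.normal(60, 8, n),
            },
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
    )
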