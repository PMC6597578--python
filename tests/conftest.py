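import numpy as np
import pandas as pd
import pytest

from ilcsig.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cohorts=3,
        cohort_sizes=(20, 25, 30),
        n_genes=300,
        n_cn_driven=20,
        n_prognostic=15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return simulate_cohorts(small_config)


@pytest.fixture
def toy_survival():
    """6-subject table with one censoring at t=2 (hand-tractable)."""
    return (
        np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        np.array([1, 0, 1, 1, 1, 1]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
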