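import numpy as np
import pandas as pd
import pytest

import braintx as bt


@pytest.fixture(scope="session")
def small_config() -> bt.SimulationConfig:
    """Small but fully featured study-like configuration."""
    return bt.SimulationConfig(seed=7, n_genes=600, n_cells_per_type=40)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return bt.simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_reference):
    return bt.simulate_bulk_cohort(small_config, small_reference)


@pytest.fixture(scope="session")
def small_profiles(small_reference):
    return bt.pseudobulk_means(small_reference, level="class")


@pytest.fixture(scope="session")
def small_pem(small_profiles):
    return bt.compute_pem(small_profiles)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 8)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(8)],
    )
    return counts


@pytest.fixture()
def toy_metadata(toy_counts) -> pd.DataFrame:
    n = toy_counts.shape[1]
    return pd.DataFrame(
        {
            "condition": ["control", "stress"] * (n // 2),
            "sex": ["M", "M", "F", "F"] * (n // 4),
            "batch": ["b1"] * (n // 2) + ["b2"] * (n // 2),
        },
        index=toy_counts.columns,
    )
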