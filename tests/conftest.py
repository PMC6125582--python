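import numpy as np
import pandas as pd
import pytest

from coexmod import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort reused across read-only tests."""
    config = SimulationConfig(
        n_samples=120,
        n_genes=600,
        module_sizes=(100, 80, 60),
        rho=0.6,
        n_trait_modules=1,
        frac_low_count=0.1,
        frac_high_cov=0.05,
        n_outliers=1,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_counts():
    """Hand-sized count matrix with controllable library sizes."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 20)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(20)],
    )
    return counts
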