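import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    """A fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(20230126)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic cohort shared across module tests."""
    from mmaomics.cohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_case=20, n_other=12, n_control=8, n_genes=250, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def identity_kinship():
    from mmaomics.lmm import Kinship

    def make(n, samples=None):
        return Kinship.from_matrix(np.eye(n), samples=samples)

    return make


@pytest.fixture(scope="session")
def expression_kinship():
    """Kinship from a doubly standardized random expression matrix (n=100)."""
    from mmaomics.lmm import Kinship, iterative_standardize, sample_kinship

    gen = np.random.default_rng(404)
    M = iterative_standardize(np.exp(gen.standard_normal((400, 100))))
    return sample_kinship(pd.DataFrame(M, columns=[f"s{i:03d}" for i in range(100)]))
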