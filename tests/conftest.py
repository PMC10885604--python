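import numpy as np
import pytest

from utr_structurome import SimConfig, analyze_dataset, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact two-level experiment: 60 genes, 30 open / 30 structured UTRs."""
    return SimConfig(n_genes=60, pairing_fraction_levels=(0.1, 0.7), seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    return analyze_dataset(
        small_dataset.transcripts,
        small_dataset.treated,
        small_dataset.untreated,
        small_dataset.covariates,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_gini(values) -> float:
    """O(n^2) pairwise-difference Gini, the independent oracle."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += abs(x[i] - x[j])
    return num / (2 * n * n * x.mean())
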