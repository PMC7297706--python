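import numpy as np
import pandas as pd
import pytest

from domdev.cohort import CohortConfig, VariantPanel, simulate_cohort_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    return VariantPanel.default(n_variants=12, mode="additive", seed=7)


@pytest.fixture(scope="session")
def small_cohort_pair():
    """Modest discovery/replication pair reused across test modules."""
    panel = VariantPanel.default(n_variants=10, mode="additive", seed=11)
    cfg = CohortConfig(panel=panel, n_discovery=12_000, n_replication=8_000,
                       heritability=0.05, seed=11)
    return simulate_cohort_pair(cfg)


def additive_share_enumeration(values3, freqs3):
    """Independent 3-genotype enumeration oracle: fraction of the genetic
    variance captured by the best linear-in-allele-count predictor."""
    v = np.asarray(values3, dtype=float)
    w = np.asarray(freqs3, dtype=float)
    g = np.array([0.0, 1.0, 2.0])
    mu_g = (w * g).sum()
    mu_v = (w * v).sum()
    cov = (w * (g - mu_g) * (v - mu_v)).sum()
    var_g = (w * (g - mu_g) ** 2).sum()
    var_v = (w * (v - mu_v) ** 2).sum()
    return (cov**2 / var_g) / var_v
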