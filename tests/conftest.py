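import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small synthetic configuration for fast structural tests."""
    from aqnet.synthetic import SyntheticConfig

    return SyntheticConfig(
        seed=11, n_genes=150, n_conditions=30, n_replicates_per_condition=2,
        module_size=10, n_genes_species2=120, n_orthologs=40,
        targets_per_set=20, peaks_per_set=40,
    )


@pytest.fixture
def toy_corr():
    """Hand-sized correlation matrix with a known tight pair (a, b)."""
    genes = list("abcdef")
    rng = np.random.default_rng(0)
    x = rng.standard_normal((6, 12))
    x[1] = 0.95 * x[0] + 0.05 * rng.standard_normal(12)  # b tracks a
    corr = np.corrcoef(x)
    return pd.DataFrame(corr, index=genes, columns=genes)
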