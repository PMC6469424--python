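import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A small random NB count matrix with two 6-sample groups."""
    n_genes, n = 200, 12
    mu = np.exp(rng.uniform(np.log(10), np.log(400), n_genes))
    size = 1 / 0.2
    m = mu[:, None] * np.ones(n)
    counts = rng.negative_binomial(size, size / (size + m))
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"),
        columns=[f"s{i:02d}" for i in range(n)],
    )
    return df


@pytest.fixture
def two_groups(small_counts):
    cols = list(small_counts.columns)
    return cols[:6], cols[6:]
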