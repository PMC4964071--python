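import numpy as np
import pytest

from varstab import FcSimConfig, simulate_fc_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """3 samples x 2 populations x 5,000 events, true cofactor exp(4)."""
    cfg = FcSimConfig(events_per_sample=5000, true_cofactor=float(np.exp(4.0)), seed=7)
    return cfg, simulate_fc_dataset(cfg)


def random_group_summaries(rng, m_range=(2, 10), n_range=(5, 500)):
    """Raw groups plus their (count, unbiased variance) summaries."""
    m = int(rng.integers(*m_range, endpoint=True))
    groups = []
    for _ in range(m):
        n = int(rng.integers(*n_range, endpoint=True))
        sd = float(rng.uniform(0.2, 5.0))
        groups.append(rng.normal(rng.uniform(-10, 10), sd, size=n))
    counts = np.array([g.size for g in groups])
    variances = np.array([np.var(g, ddof=1) for g in groups])
    return groups, counts, variances
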