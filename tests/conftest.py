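import numpy as np
import pandas as pd
import pytest

from fishwarm import GenerativeConfig, generate_dataset, generate_edge_fixtures


@pytest.fixture(scope="session")
def edge():
    """Hand-built edge-case tables with hand-enumerated expected tallies."""
    return generate_edge_fixtures()


@pytest.fixture(scope="session")
def small_bundle():
    """A quick synthetic bundle shared by tests that only read it."""
    return generate_dataset(GenerativeConfig.small(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_glmm_data(seed=42, n_groups=25, n_per=12, beta0=-0.4, beta1=1.1, sigma=0.9):
    """Small logistic random-intercept dataset with known parameters."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_per)
    x = rng.uniform(0, 1, n_groups * n_per)
    u = rng.normal(0, sigma, n_groups)
    eta = beta0 + beta1 * x + u[g]
    y = (rng.random(len(x)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"y": y, "position": x, "species": g})
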