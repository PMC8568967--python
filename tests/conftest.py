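import numpy as np
import pytest

from nectarweb import ScenarioConfig, fixture_small
from nectarweb.pipeline import prepare_dataset


@pytest.fixture(scope="session")
def mini():
    """Deterministic 4-species x 2-parasitoid x 6-plot miniature dataset."""
    return fixture_small()


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default scenario."""
    return prepare_dataset(ScenarioConfig(master_seed=42))


@pytest.fixture(scope="session")
def glmm_sim():
    """A small grouped binomial dataset with a known generating model."""
    rng = np.random.default_rng(1)
    n, strips = 27, np.repeat([1, 2, 3], 9)
    x = rng.normal(size=n)
    u = rng.normal(0, 0.5, 3)
    eta = -1.0 + 0.5 * x + u[strips - 1]
    m = np.full(n, 60)
    y = rng.binomial(m, 1.0 / (1.0 + np.exp(-eta)))
    X = np.column_stack([np.ones(n), x])
    return {"X": X, "y": y, "m": m, "strips": strips, "x": x}
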