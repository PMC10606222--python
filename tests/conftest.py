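import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kernelsurv import ScenarioConfig, SurvivalDataset, simulate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_dataset():
    """Three subjects, times (1, 2, 3), events (1, 1, 0)."""
    X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, -1.0]])
    return SurvivalDataset(X, [1.0, 2.0, 3.0], [1, 1, 0])


@pytest.fixture
def random_dataset(rng):
    """Uncensored lognormal data with a linear signal, n=60, m=3."""
    n, m = 60, 3
    X = rng.normal(size=(n, m))
    t = np.exp(X[:, 0] + 0.5 * rng.normal(size=n))
    d = np.ones(n, dtype=int)
    d[rng.random(n) < 0.25] = 0
    return SurvivalDataset(X, t, d)


@pytest.fixture(scope="session")
def series_a_small():
    """One small series-A replicate shared across tests."""
    cfg = ScenarioConfig(series="A", n_train=120, n_test=300,
                         interaction_fraction=0.5, censoring=0.0, seed=7)
    return simulate(cfg)
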