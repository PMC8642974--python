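import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_sim():
    """One full default-architecture BC3F2 simulation, shared read-only."""
    from pedsmap import default_config, simulate_population

    return simulate_population(default_config(11))


@pytest.fixture(scope="session")
def f2_sample():
    """An unselected F2 of the single-QTL cross (read-only)."""
    from pedsmap import single_qtl_config
    from pedsmap.simulate import simulate_f2

    cfg = single_qtl_config(5)
    pop = simulate_f2(cfg, 5000, np.random.default_rng(5))
    return cfg, pop
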