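import numpy as np
import pytest

import searchprime as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pools():
    """A dozen landscapes per condition, shared across tests."""
    rng = np.random.default_rng(777)
    return {c: sp.landscape_pool(c, 12, rng) for c in ("clustered", "dispersed")}


@pytest.fixture(scope="session")
def study_tables():
    """A clean synthetic cohort (no nuisance behaviour), 20 per arm."""
    cfg = sp.StudyConfig(n_per_condition=20, seed=2024, pool_size=10)
    return sp.simulate_study(cfg)


@pytest.fixture(scope="session")
def study_report(study_tables):
    data = sp.StudyData.from_tables(study_tables)
    return sp.run_all(data)
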