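import numpy as np
import pytest
from hypothesis import settings

import emascale as e

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_study():
    """A small two-arm study used across tests (12 + 12 participants)."""
    cfg = e.SyntheticConfig(n_likert=12, n_vas=12, seed=7)
    return e.apply_inclusion(e.generate_study(cfg))


@pytest.fixture(scope="session")
def small_stat_table(small_study):
    return e.compute_stat_table(small_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
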