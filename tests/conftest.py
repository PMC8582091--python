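import numpy as np
import pytest
from hypothesis import settings

from fallrisk import GeneratorConfig, generate_cohort, table1_defaults

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def complete_cohort():
    """Synthetic cohort with no missing cells (n=300, fixed seed)."""
    cfg = table1_defaults()
    cfg.n = 300
    cfg.seed = 42
    cfg.missing_rates = {}
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def gappy_cohort():
    """Synthetic cohort with the default missingness rates (n=400)."""
    cfg = table1_defaults()
    cfg.n = 400
    cfg.seed = 7
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
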