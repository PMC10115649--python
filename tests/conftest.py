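import numpy as np
import pytest

from phylogd.cohort import SimConfig, simulate_tumour


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_tumour():
    """One deterministic simulated tumour used by several suites."""
    cfg = SimConfig(sample_group="medium")
    return simulate_tumour(cfg, "T1", np.random.default_rng(11))
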