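import numpy as np
import pytest

from dgescreen.simulate import SimConfig, default_library_sizes, simulate_experiment


@pytest.fixture(scope="session")
def null_poisson_experiment():
    """All-null, Poisson, equal libraries: the calibration benchmark."""
    cfg = SimConfig(dispersion=0.0, planted_fractions={"null": 1.0}, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def default_experiment():
    """The default planted-effect simulation used for recovery checks."""
    cfg = SimConfig(seed=7)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for fast structural tests."""
    return SimConfig(
        n_genes=2_000,
        library_sizes=default_library_sizes(2_000),
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
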