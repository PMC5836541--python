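import numpy as np
import pytest

from pulsefit.synthetic import (
    SimConfig,
    TrueParams,
    simulate_experiment,
    random_barcode_library,
    random_index_codebook,
)


@pytest.fixture(scope="session")
def noiseless_run():
    """Small noiseless simulation with spread fitness effects."""
    cfg = SimConfig(n_mutants=50, periods=(6,), nb_dispersion=0.0, seed=101)
    truth = TrueParams.random(50, sd_w=0.03, seed=102)
    counts, sheet = simulate_experiment(cfg, truth)
    return cfg, truth, counts, sheet


@pytest.fixture(scope="session")
def noisy_run():
    """NB-noise simulation at the default depth with some inhomogeneous genes."""
    cfg = SimConfig(n_mutants=80, periods=(6,), depth_per_sample=1e6,
                    nb_dispersion=0.01, seed=111)
    truth = TrueParams.random(80, sd_w=0.02, frac_inhomogeneous=0.25,
                              beta3_effect=0.05, seed=112)
    counts, sheet = simulate_experiment(cfg, truth)
    return cfg, truth, counts, sheet


@pytest.fixture(scope="session")
def small_codebook():
    return random_index_codebook(8, seed=7)


@pytest.fixture(scope="session")
def small_library():
    ids = [f"mut{i:05d}" for i in range(12)]
    return random_barcode_library(ids, seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
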