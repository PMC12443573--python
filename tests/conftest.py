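import numpy as np
import pytest

from spadgwas import synthio


@pytest.fixture(scope="session")
def sim_config():
    return synthio.SimConfig(seed=1, n_snps=400)


@pytest.fixture(scope="session")
def population(sim_config):
    return synthio.simulate_genotypes(sim_config)


@pytest.fixture(scope="session")
def trial(population, sim_config):
    return synthio.simulate_spad_phenotypes(population, sim_config)


@pytest.fixture(scope="session")
def noiseless_scene(trial, sim_config):
    return synthio.render_scene(
        trial, ("E1", "W", "HS"), sim_config, noise_sd=0.0, plot_noise_sd=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
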