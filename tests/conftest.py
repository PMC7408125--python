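import pytest

from strainscope.compounds import load_compound_table
from strainscope.network import ScoringParams
from strainscope.synthetic import (
    SimulationConfig,
    make_library,
    make_production,
    simulate_spectra,
)


@pytest.fixture(scope="session")
def table1():
    return load_compound_table()


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_strains=4, compounds_per_group={"1": 2, "2": 2, "3": 2}, seed=11
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """A small but complete simulated data set shared across tests."""
    lib = make_library(small_cfg)
    production = make_production(lib, cfg=small_cfg)
    spectra = simulate_spectra(lib, production, small_cfg)
    return lib, production, spectra


@pytest.fixture(scope="session")
def default_params():
    return ScoringParams()
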