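import numpy as np
import pandas as pd
import pytest

from npdruglike import synthdata as sd


@pytest.fixture(scope="session")
def sim_cfg():
    """Small, fixed-seed study conditions shared across tests."""
    return sd.SimConfig(n_drug=200, n_np=200, n_toxin=200, seed=7)


@pytest.fixture(scope="session")
def property_table(sim_cfg):
    return sd.generate_property_tables(sim_cfg)


@pytest.fixture(scope="session")
def endpoint_table(sim_cfg):
    return sd.combined_endpoint_table(sim_cfg)


@pytest.fixture(scope="session")
def descriptor_table(sim_cfg):
    return sd.generate_descriptor_tables(sim_cfg)


@pytest.fixture(scope="session")
def fixture_mols():
    return sd.fixture_structures()
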