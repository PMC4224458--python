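import numpy as np
import pytest

from emdetwin import (AmbiguityGroup, EMConfig, PointGroup, SimulationConfig,
                      UnitCell, simulate_dataset)


@pytest.fixture(scope="session")
def pg6():
    return PointGroup.hexagonal_6()


@pytest.fixture(scope="session")
def pg1():
    return PointGroup.identity_only(friedel=False)


@pytest.fixture(scope="session")
def group2():
    return AmbiguityGroup.p63()


@pytest.fixture(scope="session")
def group1():
    return AmbiguityGroup.single()


@pytest.fixture(scope="session")
def small_cell():
    return UnitCell.hexagonal(60.0, 40.0)


@pytest.fixture(scope="session")
def sim_uniform():
    """A medium uniform-partiality dataset shared across tests."""
    cfg = SimulationConfig(n_patterns=800, seed=1234)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def sim_resdep():
    """A medium resolution-dependent-partiality dataset."""
    cfg = SimulationConfig(n_patterns=800, seed=4321,
                           partiality_model="resolution_dependent")
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth
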