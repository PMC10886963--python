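"""Shared fixtures: default geometry/optics and small cached simulations."""

import numpy as np
import pytest

import sesorsmc as smc
from sesorsmc import engine
from sesorsmc.transport import TransportConfig


@pytest.fixture(scope="session")
def model():
    return smc.TissueModel.default()


@pytest.fixture(scope="session")
def table():
    return smc.build_property_table()


@pytest.fixture(scope="session")
def small_run(model, table):
    """One modest default-config run shared by tally/invariant tests."""
    cfg = TransportConfig(n_photons=20_000, seed=42)
    return engine.run(cfg, model, table)


@pytest.fixture(scope="session")
def small_pair(model, table):
    """Paired property-update on/off runs with common random numbers."""
    on = engine.run(
        TransportConfig(n_photons=20_000, seed=5, property_update=True),
        model, table,
    )
    off = engine.run(
        TransportConfig(n_photons=20_000, seed=5, property_update=False),
        model, table,
    )
    return on, off


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
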