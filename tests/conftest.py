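"""Shared fixtures: one default rivalry run and one recovery-grade run.

The expensive simulations are session-scoped so every test file reuses
them; seeds are fixed constants so the whole suite is reproducible.
"""

import numpy as np
import pytest
from hypothesis import settings

import rivalnet as rn

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from rivalnet.experiments import simulate_realization


@pytest.fixture(scope="session")
def params():
    return rn.ModelParameters()


@pytest.fixture(scope="session")
def gratings():
    return rn.rivalry_gratings()


@pytest.fixture(scope="session")
def small_params():
    """Reduced network for cheap structural / determinism tests."""
    return rn.ModelParameters(N_E=250, N_I=250, K=30)


@pytest.fixture(scope="session")
def small_gratings():
    # 50x50 images so n = 10 * N_E for the small network
    return rn.rivalry_gratings(dims=(50, 50), period=10)


@pytest.fixture(scope="session")
def rivalry_run(params, gratings):
    """One 10 s default rivalry run with currents and voltage statistics."""
    realization, result = simulate_realization(
        params, gratings, duration=10.0, seed=np.random.SeedSequence([404, 0]),
        record_voltage=True, record_currents=True,
    )
    return realization, result


@pytest.fixture(scope="session")
def network(params, gratings):
    """A default-parameter network realization (no simulation)."""
    return rn.build_network(params, gratings, seed=np.random.SeedSequence([505, 0]))
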