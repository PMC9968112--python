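import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pfasim as pf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_fixture() -> pf.Fixture:
    return pf.make_reference_fixture(seed=0)


@pytest.fixture(scope="session")
def reference_mesh(reference_fixture) -> pf.SimMesh:
    return reference_fixture.mesh


@pytest.fixture(scope="session")
def materials() -> pf.MaterialSet:
    return pf.default_materials()


@pytest.fixture(scope="session")
def short_protocol() -> pf.PulseProtocol:
    # two pulses with a 100 ms interval: resolves pulse heating and
    # interval cooling while keeping a run under a second
    return pf.PulseProtocol(amplitude=1000.0, interval=0.1, count=2)


@pytest.fixture(scope="session")
def reference_potential(reference_mesh, materials) -> pf.PotentialSolution:
    """Potential solve on the reference mesh at 1000 V / 37 degC."""
    return pf.solve_potential(reference_mesh, materials, 37.0, 1000.0)


@pytest.fixture(scope="session")
def cycle_velocity(reference_mesh, reference_fixture):
    cfg = pf.RunConfig()
    return pf.precompute_cycle_velocity(reference_mesh, cfg, reference_fixture.waveform)
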