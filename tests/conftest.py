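import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pdcircuit as pc

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def healthy_landscape():
    """Stationary density/flux/thermo at the healthy weights (auto zoom grid)."""
    density = pc.steady_state_density(pc.HEALTHY)
    flux = pc.flux_field(density, pc.HEALTHY)
    thermo = pc.entropy_production_rate(density, flux)
    return density, flux, thermo


@pytest.fixture(scope="session")
def pd_landscape():
    """Stationary density/flux/thermo at the Parkinsonian weights (full box)."""
    density = pc.steady_state_density(pc.PARKINSONIAN)
    flux = pc.flux_field(density, pc.PARKINSONIAN)
    thermo = pc.entropy_production_rate(density, flux)
    return density, flux, thermo


@pytest.fixture(scope="session")
def equilibrium_landscape():
    """Gradient (detailed-balance) oracle system on the full state box.

    F = -grad V with a quadratic V centred mid-box; its stationary state
    carries no flux and produces no entropy.
    """

    def drift(x, y):
        return -1.0 * (x - 60.0), -1.0 * (y - 80.0)

    grid = pc.GridSpec.full_state_space()
    p = pc.stationary_density(drift, grid, 5.0)
    density = pc.GridDensity(grid, p, -np.log(np.maximum(p / grid.cell_area, 1e-12)))
    flux = pc.flux_field(density, drift_fn=drift, noise=pc.NoiseModel(5.0))
    thermo = pc.entropy_production_rate(density, flux, pc.NoiseModel(5.0))
    return density, flux, thermo


@pytest.fixture(scope="session")
def pd_deterministic_trajectory():
    """5 s noise-free Parkinsonian trajectory (shared by several tests)."""
    return pc.simulate_deterministic(pc.PARKINSONIAN, t_end=5.0, dt_out=5e-4)
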