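import numpy as np
import pytest

import sphereq as sq
from sphereq.experiments import demo_membrane, sphere_for_ratio

RATIOS = (0.25, 0.5, 1.0, 2**0.5, 2.0)


@pytest.fixture(scope="session")
def membrane():
    return demo_membrane()


@pytest.fixture(scope="session")
def adipocyte():
    """(membrane, geometry, electrode, stimulus) for the canonical adipocyte."""
    return sq.loads_config(sq.adipocyte_config())


@pytest.fixture(scope="session")
def oracle_profiles(membrane):
    """Steady profiles from all three routes across the radius regimes.

    Computed once per session: {rho/lambda: (legendre, shooting, finite_volume)}
    on a shared 201-node grid (the finite-volume route on a finer grid,
    interpolated back).
    """
    electrode = sq.ElectrodeConfig(theta_a=0.1)
    grid = sq.AngularGrid(0.1, 201)
    out = {}
    for ratio in RATIOS:
        geom = sphere_for_ratio(membrane, ratio)
        leg = sq.steady_profile(membrane, geom, electrode, 1e-10, grid)
        sho = sq.shooting_oracle(membrane, geom, electrode, 1e-10, grid)
        fv = sq.discrete_steady_profile(
            membrane, geom, electrode, 1e-10, sq.AngularGrid(0.1, 2001)
        )
        out[ratio] = (leg, sho, fv)
    return out


def fv_on_grid(fv_profile, grid):
    """Interpolate a finite-volume profile onto a coarser grid for comparison."""
    return np.interp(grid.nodes, fv_profile.grid.nodes, fv_profile.V)
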