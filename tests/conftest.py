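import numpy as np
import pytest

from blisterflow.geometry_synth import (
    CenterlineSpec,
    RadiusProfile,
    make_tube_mesh,
)
from blisterflow.projection_recon import cap_openings


@pytest.fixture(scope="session")
def straight_tube():
    """Straight 4 mm cylinder, 20 mm long, open-ended."""
    spec = CenterlineSpec(kind="straight", length_mm=20.0, n_samples=50)
    return make_tube_mesh(spec, RadiusProfile.constant(2.0), 32)


@pytest.fixture(scope="session")
def siphon_tube():
    """Default gently curved siphon-like tube (4 mm diameter)."""
    return make_tube_mesh(CenterlineSpec(n_samples=200), RadiusProfile.constant(2.0), 32)


@pytest.fixture(scope="session")
def capped_cylinder(straight_tube):
    return cap_openings(straight_tube.copy())


@pytest.fixture(scope="session")
def poiseuille_solution():
    """Stokes-mode straight-tube solution on a coarse (fast) grid.

    Shared across solver and post-processing unit tests; the full
    25-cells-per-diameter run lives in the acceptance suite.
    """
    from blisterflow.flow_solver import solve_steady, voxelize

    spec = CenterlineSpec(kind="straight", length_mm=10.0, n_samples=30)
    tube = make_tube_mesh(spec, RadiusProfile.constant(2.0), 48)
    grid = voxelize(cap_openings(tube), cells_per_diameter=13)
    field = solve_steady(grid, stokes=True, max_iter=3000)
    return grid, field


def analytic_poiseuille(props=None, bc=None, radius=2e-3):
    from blisterflow.flow_solver import BoundaryConditions, FluidProperties

    props = props or FluidProperties()
    bc = bc or BoundaryConditions()
    q = bc.flow_rate
    return {
        "peak_velocity": 2.0 * q / (np.pi * radius**2),
        "pressure_drop_per_length": 8.0 * props.dynamic_viscosity * q / (np.pi * radius**4),
        "wss": 4.0 * props.dynamic_viscosity * q / (np.pi * radius**3),
    }
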