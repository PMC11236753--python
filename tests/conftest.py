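"""Shared fixtures: small solved fields and fiber populations.

Everything is generated programmatically at test time with fixed seeds;
problem sizes are kept small (coarse grids, tens of fibers) so the whole
suite runs quickly on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from festwin.cable import CableParams, derive_node_constants
from festwin.fibers import DiameterDistribution, internodal_distance_um, place_fibers
from festwin.grid import homogeneous_cuboid_grid
from festwin.nep import ROISpec
from festwin.solver import solve_potential


@pytest.fixture(scope="session")
def cable_params() -> CableParams:
    return CableParams.from_fixture()


@pytest.fixture(scope="session")
def cuboid_field():
    """Patch-electrode cuboid: a cheap but genuinely 3D solved field.

    40 x 40 x 60 mm block of muscle-like medium (sigma = 1/3 S/m) with a
    10 x 10 mm active patch on the z=0 face and a full sink face at z=60.
    """
    grid = homogeneous_cuboid_grid((40.0, 40.0, 60.0), 2.0, 1.0 / 3.0,
                                   electrode_patch_mm=(10.0, 10.0))
    return solve_potential(grid, 1.0)


@pytest.fixture(scope="session")
def demo_roi() -> ROISpec:
    """ROI centred in the cuboid, axis along z."""
    return ROISpec("DEMO", np.array([20.0, 20.0, 35.0]),
                   np.array([0.0, 0.0, 1.0]), (6.0, 4.0), 20.0)


@pytest.fixture(scope="session")
def demo_population(demo_roi):
    return place_fibers(demo_roi, n=60, dist=DiameterDistribution(), seed=11)


def point_source_fiber(d_um: float, depth_mm: float = 10.0,
                       lateral_mm: float = 0.0, length_mm: float = 20.0,
                       rho_ohm_m: float = 3.0):
    """Unit-current cathodic node potentials for a straight fiber under a
    point source; returns (ve_unit_mV, delta_x_um, node_x_mm)."""
    from festwin.af import point_source_potential_mV

    dx_um = float(internodal_distance_um(d_um))
    dx_mm = dx_um / 1000.0
    half = length_mm / 2.0
    x = np.arange(-half, half + 1e-9, dx_mm)
    nodes = np.zeros((len(x), 3))
    nodes[:, 0] = x
    src = np.array([lateral_mm, 0.0, depth_mm])
    ve = point_source_potential_mV(nodes, src, rho_ohm_m, -1.0)
    return ve, dx_um, x


def bisect_threshold(ve_unit_mV, pw_us, constants, params, rel_tol=1e-3):
    """Independent threshold search by bisection on the simulated verdict."""
    from festwin.cable import simulate_lc
    from festwin.pulse import StimulusPulse

    def activated(amp: float) -> bool:
        pulse = StimulusPulse(amp, pw_us)
        t = np.arange(0.0, pulse.duration_us + params.post_pulse_us + 1e-9,
                      params.dt_us)
        ve = np.outer(np.asarray(ve_unit_mV), pulse.waveform(t))
        return simulate_lc(ve, t, constants, params).verdict.activated

    lo, hi = 1e-3, 1.0
    for _ in range(60):
        if activated(hi):
            break
        lo, hi = hi, hi * 2.0
    else:  # pragma: no cover
        return float("inf")
    while (hi - lo) / lo > rel_tol:
        mid = 0.5 * (lo + hi)
        if activated(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
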