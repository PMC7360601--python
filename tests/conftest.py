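"""Shared fixtures: meshes, phantoms and forward-generated observations.

Expensive objects (the standard 500 µm mesh, a simulated noiseless interval
and its sequential fit) are session-scoped so the oracle-style checks can
share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spherofit.forward import (
    BiophysicalParams,
    CellularityField,
    SolverConfig,
    material_from_core,
    simulate_interval,
)
from spherofit.inverse import FitConfig, ObservationPair, fit_interval
from spherofit.mesh import PixelGrid, build_mesh
from spherofit.phantom import PhantomConfig, make_phantom

# the untreated hour-36 group-mean triplet used as generating ground truth
TRUTH = dict(D0=399.46, k=1.18e-2, lam=-1596.31)


@pytest.fixture(scope="session")
def mesh500():
    """Standard field-of-view mesh: 500 × 500 µm, 45 µm target edges."""
    return build_mesh((500.0, 500.0), 45.0)


@pytest.fixture(scope="session")
def grid100():
    return PixelGrid(100, 100, 5.0)


@pytest.fixture(scope="session")
def phantom7():
    return make_phantom(PhantomConfig(rng_seed=7))


def radial_cellularity(mesh, core_radius=100.0, width=20.0, peak=1.0):
    r = np.hypot(mesh.node_coords[:, 0] - 250.0, mesh.node_coords[:, 1] - 250.0)
    return peak * np.where(
        r <= core_radius, 1.0, np.exp(-((r - core_radius) ** 2) / (2 * width**2))
    )


@pytest.fixture(scope="session")
def spheroid_state(mesh500):
    """Initial cellularity profile and the core-stiffened material map."""
    n0 = radial_cellularity(mesh500)
    material = material_from_core(mesh500, n0)
    return CellularityField(n0, 24.0), material


@pytest.fixture(scope="session")
def noiseless_interval(mesh500, spheroid_state):
    """One simulated 12 h interval at the generating truth triplet."""
    n0, material = spheroid_state
    params = BiophysicalParams(**TRUTH, interval=(24.0, 36.0))
    result = simulate_interval(n0, params, material, mesh500, SolverConfig())
    obs = ObservationPair(n0, result.n_end, result.displacement)
    return obs, result


@pytest.fixture(scope="session")
def noiseless_fit(mesh500, spheroid_state, noiseless_interval):
    """Sequential fit of the noiseless interval from 2x-perturbed inits."""
    _, material = spheroid_state
    obs, _ = noiseless_interval
    return fit_interval(
        obs, mesh500, material, SolverConfig(),
        FitConfig(init_d0=2 * TRUTH["D0"], init_k=2 * TRUTH["k"]),
    )
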