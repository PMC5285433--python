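"""Shared fixtures: default parameters, meshes and the long scenario runs.

The two 400-day coarse-mesh scenario runs (high and low myofibroblast
apoptosis) are expensive, so they are computed once per session and shared
by the regression, positivity and thickness-contrast tests.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from scarsim import fem
from scarsim.geometry import DomainSpec, WoundSpec
from scarsim.mesh import generate_mesh
from scarsim.parameters import ParameterSet
from scarsim.solver import SolverOptions, simulate


def heat_equation_error(mesh, dt, t_end):
    """Backward-Euler Galerkin march of u_t = lap(u) for the separable mode
    exp(-2 pi^2 t) sin(pi x) sin(pi y) on the unit square; returns the final
    max-node error (used for the time/space convergence-order studies)."""
    pts, tri = mesh.nodes_ref, mesh.triangles
    u = np.sin(np.pi * pts[:, 0]) * np.sin(np.pi * pts[:, 1])
    K = fem.stiffness(pts, tri, 1.0)
    M = fem.consistent_mass(pts, tri)
    bnd = mesh.boundary_nodes()
    A = (M / dt + K).tolil()
    A[bnd, :] = 0.0
    A[bnd, bnd] = 1.0
    solve = sp.linalg.factorized(A.tocsc())
    t = 0.0
    while t < t_end - 1e-12:
        b = M @ u / dt
        b[bnd] = 0.0
        u = solve(b)
        t += dt
    exact = (np.exp(-2.0 * np.pi**2 * t_end)
             * np.sin(np.pi * pts[:, 0]) * np.sin(np.pi * pts[:, 1]))
    return np.abs(u - exact).max()

COARSE_EDGE = 0.1  # cm, the coarse study resolution used in the long runs


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def domain() -> DomainSpec:
    return DomainSpec()


@pytest.fixture(scope="session")
def coarse_mesh(domain):
    return generate_mesh(domain, COARSE_EDGE, seed=0)


@pytest.fixture(scope="session")
def unit_square_mesh():
    """Structured mesh of the unit square for manufactured-solution tests."""
    return generate_mesh(DomainSpec(y_min=0.0, y_max=1.0, z_min=0.0, z_max=1.0), 0.1, seed=0)


@pytest.fixture(scope="session")
def nowound_run(coarse_mesh, params):
    """20-day run from the unwounded equilibrium (no wound forced)."""
    return simulate(coarse_mesh, params, wound=None, duration=20.0)


@pytest.fixture(scope="session")
def high_apoptosis_run(coarse_mesh):
    """400-day wound run, high myofibroblast apoptosis (normal-scar regime)."""
    p = ParameterSet(delta_M=6e-2)
    return simulate(coarse_mesh, p, WoundSpec(half_width=4.0), duration=400.0)


@pytest.fixture(scope="session")
def low_apoptosis_run(coarse_mesh):
    """400-day wound run, low myofibroblast apoptosis (hypertrophic regime)."""
    p = ParameterSet(delta_M=2e-3)
    return simulate(coarse_mesh, p, WoundSpec(half_width=4.0), duration=400.0)


@pytest.fixture(scope="session")
def tracked_node(coarse_mesh) -> int:
    """Index of the mesh node nearest the tracked material point (0, -0.075)."""
    return int(np.argmin(np.linalg.norm(coarse_mesh.nodes_ref - [0.0, -0.075], axis=1)))
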