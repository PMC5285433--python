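"""FCT limiter: reference-limiter oracle, maximum principle, positivity.

The production limiter is vectorized over the sparse edge graph; the oracle
here recomputes Zalesak's coefficients with plain per-node Python loops from
the same fluxes and bounds, completely independently of the sparse
implementation.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from scarsim import fem
from scarsim.fct import artificial_diffusion, fct_transport_step, zalesak_coefficients
from scarsim.geometry import DomainSpec
from scarsim.mesh import generate_mesh
from scarsim.solver import _mesh_edges


def reference_zalesak(edges, f, z_low, z_old, m, dt):
    """Loop-based Zalesak limiter (independent oracle)."""
    n = len(z_low)
    neigh = {i: set() for i in range(n)}
    for (i, j) in edges:
        neigh[i].add(j)
        neigh[j].add(i)
    hi = np.empty(n)
    lo = np.empty(n)
    for i in range(n):
        cand = [max(z_low[k], z_old[k]) for k in neigh[i] | {i}]
        hi[i] = max(cand)
        cand = [min(z_low[k], z_old[k]) for k in neigh[i] | {i}]
        lo[i] = min(cand)
    Pp = np.zeros(n)
    Pm = np.zeros(n)
    for (i, j), fij in zip(edges, f):
        Pp[i] += max(fij, 0.0)
        Pm[i] += min(fij, 0.0)
        Pp[j] += max(-fij, 0.0)
        Pm[j] += min(-fij, 0.0)
    Rp = np.ones(n)
    Rm = np.ones(n)
    for i in range(n):
        if Pp[i] > 0:
            Rp[i] = min(1.0, (hi[i] - z_low[i]) * m[i] / dt / Pp[i])
        if Pm[i] < 0:
            Rm[i] = min(1.0, (lo[i] - z_low[i]) * m[i] / dt / Pm[i])
    alpha = np.empty(len(f))
    for k, ((i, j), fij) in enumerate(zip(edges, f)):
        alpha[k] = min(Rp[i], Rm[j]) if fij >= 0 else min(Rm[i], Rp[j])
    return alpha


@pytest.fixture(scope="module")
def strip():
    """A thin 1D-like strip mesh (advection fixture)."""
    dom = DomainSpec(y_min=0.0, y_max=2.0, z_min=0.0, z_max=0.2)
    mesh = generate_mesh(dom, 0.2, seed=0)
    return mesh


def _transport_pieces(mesh, velocity):
    pts, tri = mesh.nodes_ref, mesh.triangles
    w = np.tile(velocity, (mesh.n_nodes, 1))
    K = -fem.advection_divergence(pts, tri, w).tocsr()
    return {
        "edges": _mesh_edges(tri),
        "m_old": fem.lumped_mass(pts, tri),
        "m_new": fem.lumped_mass(pts, tri),
        "mass_consistent": fem.consistent_mass(pts, tri),
        "K": K,
        "dirichlet_idx": np.array([], dtype=int),
        "dirichlet_val": np.array([]),
    }


class TestArtificialDiffusion:
    def test_removes_negative_offdiagonals_with_zero_row_sums(self, strip):
        pieces = _transport_pieces(strip, np.array([1.0, 0.0]))
        K = pieces["K"]
        D = artificial_diffusion(K)
        L = (K + D).tocoo()
        off = L.row != L.col
        assert np.all(L.data[off] >= -1e-14)
        assert np.allclose(np.asarray(D.sum(axis=1)).ravel(), 0.0, atol=1e-14)
        assert (abs(D - D.T) > 1e-14).nnz == 0  # symmetric


class TestLimiterAgainstReference:
    def test_matches_loop_reference_on_advected_step(self, strip):
        """Limiter coefficients on a discontinuous advected profile equal the
        independently coded per-node reference."""
        pieces = _transport_pieces(strip, np.array([1.0, 0.0]))
        pts = strip.nodes_ref
        z_old = np.where(pts[:, 0] < 1.0, 1.0, 0.0)
        dt = 0.05
        edges = pieces["edges"]
        D = artificial_diffusion(pieces["K"])
        L = (pieces["K"] + D).tocsr()
        A = sp.diags(pieces["m_new"] / dt) - L
        z_low = sp.linalg.spsolve(A.tocsc(), pieces["m_old"] * z_old / dt)
        ii, jj = edges[:, 0], edges[:, 1]
        m_ij = np.asarray(pieces["mass_consistent"][ii, jj]).ravel()
        d_ij = np.asarray(D[ii, jj]).ravel()
        zdot = (z_low - z_old) / dt
        f = m_ij * (zdot[ii] - zdot[jj]) + d_ij * (z_low[ii] - z_low[jj])
        f[f * (z_low[jj] - z_low[ii]) > 0.0] = 0.0
        alpha = zalesak_coefficients(edges, f, z_low, z_old, pieces["m_new"], dt)
        alpha_ref = reference_zalesak([tuple(e) for e in edges], f, z_low, z_old,
                                      pieces["m_new"], dt)
        assert np.allclose(alpha, alpha_ref, atol=1e-13)
        assert np.all((alpha >= 0.0) & (alpha <= 1.0))

    def test_smooth_profile_needs_no_interior_limiting(self, strip):
        """A gentle linear profile advected one step leaves every interior
        coefficient at one: away from the in/outflow boundaries the
        correction reduces to the Galerkin scheme."""
        pieces = _transport_pieces(strip, np.array([0.05, 0.0]))
        pts = strip.nodes_ref
        z_old = 1.0 + 0.1 * pts[:, 0]
        dt = 0.01
        edges = pieces["edges"]
        D = artificial_diffusion(pieces["K"])
        L = (pieces["K"] + D).tocsr()
        A = sp.diags(pieces["m_new"] / dt) - L
        z_low = sp.linalg.spsolve(A.tocsc(), pieces["m_old"] * z_old / dt)
        ii, jj = edges[:, 0], edges[:, 1]
        m_ij = np.asarray(pieces["mass_consistent"][ii, jj]).ravel()
        d_ij = np.asarray(D[ii, jj]).ravel()
        zdot = (z_low - z_old) / dt
        f = m_ij * (zdot[ii] - zdot[jj]) + d_ij * (z_low[ii] - z_low[jj])
        alpha = zalesak_coefficients(edges, f, z_low, z_old, pieces["m_new"], dt)
        bnd = np.zeros(strip.n_nodes, dtype=bool)
        bnd[strip.boundary_nodes("B.II")] = True
        bnd[strip.boundary_nodes("B.IV")] = True
        interior_edge = ~(bnd[ii] | bnd[jj])
        assert interior_edge.any()
        assert np.all(alpha[interior_edge] == pytest.approx(1.0))


class TestMaximumPrincipleAndPositivity:
    def test_step_profile_stays_within_bounds(self, strip):
        pieces = _transport_pieces(strip, np.array([1.0, 0.0]))
        pts = strip.nodes_ref
        z = np.where(np.abs(pts[:, 0] - 0.7) < 0.3, 1.0, 0.0)
        for _ in range(8):
            z, _ = fct_transport_step(
                dt=0.05, z_old=z,
                production=np.zeros_like(z), destruction=np.zeros_like(z),
                **pieces,
            )
            assert z.min() >= 0.0
            assert z.max() <= 1.0 + 1e-10

    def test_patankar_reaction_update_keeps_positivity_for_large_steps(self, strip):
        pieces = _transport_pieces(strip, np.array([0.5, 0.0]))
        z = np.full(strip.n_nodes, 1e-3)
        destr = np.full(strip.n_nodes, 50.0)  # stiff decay
        prod = np.zeros(strip.n_nodes)
        z_new, _ = fct_transport_step(dt=10.0, z_old=z, production=prod,
                                      destruction=destr, **pieces)
        assert np.all(z_new >= 0.0)
        assert np.all(z_new <= z.max())

    def test_dirichlet_rows_pinned_exactly(self, strip):
        pieces = _transport_pieces(strip, np.array([1.0, 0.0]))
        left = strip.boundary_nodes("B.IV")
        pieces["dirichlet_idx"] = left
        pieces["dirichlet_val"] = np.full(left.shape, 2.0)
        z = np.zeros(strip.n_nodes)
        z_new, _ = fct_transport_step(dt=0.1, z_old=z, production=np.zeros_like(z),
                                      destruction=np.zeros_like(z), **pieces)
        assert np.allclose(z_new[left], 2.0)
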