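"""Linear-triangle finite-element operators on the (moving) mesh.

All operators are assembled on whichever nodal coordinate set is passed in,
so the same routines serve the reference and the current configuration of
the moving grid.  Interior integrals use the second-order Newton-Cotes
(vertex) rule, which is exact for the products of linear basis functions
against element-wise constants that appear here; boundary line integrals use
the two-point Gauss rule.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "p1_geometry",
    "lumped_mass",
    "consistent_mass",
    "stiffness",
    "advection_divergence",
    "recover_gradient",
    "element_gradients",
    "integrate_vertex_rule",
    "EDGE_GAUSS_POINTS",
    "edge_gauss",
]

# two-point Gauss rule on [0, 1]: exact for cubics
EDGE_GAUSS_POINTS = (0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0))
EDGE_GAUSS_WEIGHTS = (0.5, 0.5)


def p1_geometry(points: np.ndarray, tri: np.ndarray):
    """Element areas (m,) and basis gradients (m, 3, 2) of a P1 triangulation."""
    a = points[tri[:, 0]]
    b = points[tri[:, 1]]
    c = points[tri[:, 2]]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area = 0.5 * det
    grads = np.empty((tri.shape[0], 3, 2))
    grads[:, 0, 0] = b[:, 1] - c[:, 1]
    grads[:, 0, 1] = c[:, 0] - b[:, 0]
    grads[:, 1, 0] = c[:, 1] - a[:, 1]
    grads[:, 1, 1] = a[:, 0] - c[:, 0]
    grads[:, 2, 0] = a[:, 1] - b[:, 1]
    grads[:, 2, 1] = b[:, 0] - a[:, 0]
    grads /= det[:, None, None]
    return area, grads


def lumped_mass(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Row-sum (vertex-rule) lumped mass vector (n,)."""
    area, _ = p1_geometry(points, tri)
    m = np.zeros(points.shape[0])
    for k in range(3):
        np.add.at(m, tri[:, k], area / 3.0)
    return m


def consistent_mass(points: np.ndarray, tri: np.ndarray) -> sp.csr_matrix:
    """Consistent P1 mass matrix (needed for the FCT antidiffusive fluxes)."""
    area, _ = p1_geometry(points, tri)
    n = points.shape[0]
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            vals.append(area * ((2.0 if i == j else 1.0) / 12.0))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def stiffness(points: np.ndarray, tri: np.ndarray, coeff_elem) -> sp.csr_matrix:
    """Diffusion stiffness ``K_ij = sum_e k_e A_e grad(phi_i).grad(phi_j)``.

    ``coeff_elem`` is the (possibly field-dependent) diffusivity per element.
    """
    area, grads = p1_geometry(points, tri)
    coeff = np.broadcast_to(np.asarray(coeff_elem, dtype=float), area.shape)
    n = points.shape[0]
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            vals.append(coeff * area * np.einsum("ek,ek->e", grads[:, i], grads[:, j]))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def advection_divergence(points: np.ndarray, tri: np.ndarray, w_nodal: np.ndarray) -> sp.csr_matrix:
    """Group finite-element divergence operator for ``div(z w)``.

    With the group approximation ``z w ~ sum_j z_j w_j phi_j`` the Galerkin
    term ``int phi_i div(z w)`` becomes ``C_ij z_j`` with
    ``C_ij = sum_e (A_e/3) w_j . grad(phi_j)|_e`` for each vertex i of e
    (vertex quadrature on phi_i).  Used for the chemotactic drift.
    """
    area, grads = p1_geometry(points, tri)
    n = points.shape[0]
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            wj = w_nodal[tri[:, j]]
            val = (area / 3.0) * np.einsum("ek,ek->e", wj, grads[:, j])
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            vals.append(val)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def element_gradients(points: np.ndarray, tri: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Piecewise-constant gradient of a nodal field, per element (m, 2)."""
    _, grads = p1_geometry(points, tri)
    return np.einsum("eka,ek->ea", grads, z[tri])


def recover_gradient(points: np.ndarray, tri: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Variational (lumped L2-projection) gradient recovery to the nodes.

    Projects the element-wise constant gradients onto the nodal P1 basis with
    the lumped mass; exact for globally linear fields at every node,
    including boundary nodes.
    """
    area, _ = p1_geometry(points, tri)
    ge = element_gradients(points, tri, z)
    num = np.zeros_like(points)
    den = np.zeros(points.shape[0])
    for k in range(3):
        np.add.at(num, tri[:, k], (area / 3.0)[:, None] * ge)
        np.add.at(den, tri[:, k], area / 3.0)
    return num / den[:, None]


def integrate_vertex_rule(points: np.ndarray, tri: np.ndarray, nodal: np.ndarray) -> float:
    """Domain integral of a nodal field by the vertex (Newton-Cotes) rule."""
    area, _ = p1_geometry(points, tri)
    return float((area / 3.0 * nodal[tri].sum(axis=1)).sum())


def edge_gauss(p0: np.ndarray, p1: np.ndarray):
    """Two-point Gauss data on segments: points (k, 2, 2), weights incl. |ds|.

    Returns ``(xg, wg, tangent, length)`` with ``xg[:, q]`` the q-th Gauss
    point of each segment and ``wg[:, q]`` its weight times the segment
    length.
    """
    p0 = np.atleast_2d(p0)
    p1 = np.atleast_2d(p1)
    d = p1 - p0
    length = np.linalg.norm(d, axis=1)
    xg = np.stack([p0 + s * d for s in EDGE_GAUSS_POINTS], axis=1)
    wg = np.stack([w * length for w in EDGE_GAUSS_WEIGHTS], axis=1)
    return xg, wg, d, length
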