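"""Segregated moving-grid solver for the coupled wound-healing system.

Each backward-Euler time step runs a fixed-point defect-correction loop:

1. advance the constituents (fibroblasts N, myofibroblasts M, signal c,
   collagen rho) on the current mesh-position guess with the FCT limiter and
   Patankar source splitting (positivity-preserving for any step size);
2. solve the quasi-static finite-strain force balance for the total
   displacement, given the updated myofibroblast and collagen fields;
3. move the mesh-position guess to the new displaced configuration.

The loop repeats until the relative inter-iterate differences drop below
``tol_fp``; in the limit the step is the fully implicit backward-Euler step
of the coupled system.  Accepted steps are refined by a local extrapolation
(two-step predictor) whose difference from the backward-Euler solution also
drives the adaptive step-size controller.

The mesh is material (fully Lagrangian): nodes move with the displacement
increment, so the advective term ``div(z v)`` of the conservation equations
is carried by the old/new lumped mass matrices and no relative convection
remains; the only discretized fluxes are Fickian dispersal and chemotaxis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .fct import FCTReport, fct_transport_step
from .geometry import WoundSpec, initial_state
from .kinetics import (
    patankar_split_collagen,
    patankar_split_fibroblast,
    patankar_split_myofibroblast,
    patankar_split_signal,
)
from .mechanics import DeformationError, traction_stress
from .mesh import MeshInversionError, TriMesh, move_mesh
from .parameters import ParameterSet

__all__ = [
    "SolverOptions",
    "StateFields",
    "StepControl",
    "SolveReport",
    "SimulationResult",
    "MechanicsError",
    "StepRejected",
    "solve_mechanics",
    "assemble_constituent_system",
    "advance_constituents",
    "defect_correction_step",
    "adapt_timestep",
    "simulate",
    "save_checkpoint",
    "load_checkpoint",
]

CONSTITUENTS = ("N", "M", "c", "rho")


class MechanicsError(RuntimeError):
    """Newton iteration for the force balance failed to converge."""


class StepRejected(RuntimeError):
    """Signal that the current time step must be rejected and retried."""


@dataclass(frozen=True)
class SolverOptions:
    """Numerical tolerances and controller settings (all configurable)."""

    tol_fp: float = 1e-6          # defect-correction inter-iterate tolerance
    tol_residual: float = 1e-6    # linear-solve relative residual bound
    tol_mech: float = 1e-8        # mechanics Newton relative residual
    max_fp_iter: int = 50
    newton_max_iter: int = 30
    lte_tol: float = 1e-3         # local-truncation-error tolerance (scaled)
    dt_init: float = 1e-2         # day
    dt_min: float = 1e-8          # day
    dt_max: float = 5.0           # day
    safety: float = 0.9
    shrink_min: float = 0.1
    grow_max: float = 2.0
    fd_step: float = 1e-6         # cm, tangent finite-difference step


@dataclass
class StepControl:
    """Adaptive time-step state."""

    dt: float
    tol: float = 1e-3
    dt_min: float = 1e-8
    dt_max: float = 5.0
    safety: float = 0.9
    shrink_min: float = 0.1
    grow_max: float = 2.0
    n_accepted: int = 0
    n_rejected: int = 0


@dataclass
class StateFields:
    """Nodal constituent fields at one time instant (the mesh carries u, v)."""

    time: float
    N: np.ndarray
    M: np.ndarray
    c: np.ndarray
    rho: np.ndarray

    def copy(self) -> "StateFields":
        return StateFields(self.time, self.N.copy(), self.M.copy(), self.c.copy(), self.rho.copy())

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"N": self.N, "M": self.M, "c": self.c, "rho": self.rho}


@dataclass
class SolveReport:
    """Per-step diagnostics appended to the simulation log."""

    time: float
    dt: float
    accepted: bool
    fp_iterations: int
    newton_iterations: int
    lte_estimate: float
    max_residual: float
    fct_limited_edges: int
    min_field_values: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationResult:
    """Accepted-step history of a run."""

    times: list[float]
    states: list[StateFields]
    coords: list[np.ndarray]          # current nodal coordinates per stored step
    mesh: TriMesh                     # final mesh (reference coords + connectivity)
    reports: list[SolveReport]

    @property
    def final(self) -> StateFields:
        return self.states[-1]


# ---------------------------------------------------------------------------
# mechanics: finite-strain residual, numerical tangent, damped Newton
# ---------------------------------------------------------------------------

def _signed_areas(x_elem: np.ndarray) -> np.ndarray:
    a, b, c = x_elem[:, 0], x_elem[:, 1], x_elem[:, 2]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))


def _interior_residual(u_elem, X_elem, two_C1, two_D1, psi_elem, collect_load=False):
    """Element residual contributions (m, 3, 2) on the current configuration.

    ``u_elem`` are per-element nodal displacements; the current coordinates
    are ``X_elem + u_elem``, so differentiating w.r.t. ``u_elem`` captures
    the full geometric nonlinearity.  The neo-Hookean stress is evaluated in
    fused scalar 2x2 arithmetic (this is the hot path of the tangent
    assembly; a test pins it against :func:`scarsim.mechanics.cauchy_stress`).
    With ``collect_load`` the traction-stress part is returned separately
    (used as the Newton convergence reference force).
    """
    x = X_elem + u_elem
    a, b, c = x[:, 0], x[:, 1], x[:, 2]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    if np.any(det <= 0.0):
        raise DeformationError("element inverted")
    area = 0.5 * det
    grads = np.empty_like(u_elem)  # (m, 3, 2)
    grads[:, 0, 0] = b[:, 1] - c[:, 1]
    grads[:, 0, 1] = c[:, 0] - b[:, 0]
    grads[:, 1, 0] = c[:, 1] - a[:, 1]
    grads[:, 1, 1] = a[:, 0] - c[:, 0]
    grads[:, 2, 0] = a[:, 1] - b[:, 1]
    grads[:, 2, 1] = b[:, 0] - a[:, 0]
    grads /= det[:, None, None]
    # Eulerian displacement gradient components g_ij = du_i/dx_j
    g00 = (u_elem[:, :, 0] * grads[:, :, 0]).sum(1)
    g01 = (u_elem[:, :, 0] * grads[:, :, 1]).sum(1)
    g10 = (u_elem[:, :, 1] * grads[:, :, 0]).sum(1)
    g11 = (u_elem[:, :, 1] * grads[:, :, 1]).sum(1)
    # Almansi strain e = (g + g^T - g^T g)/2, then A = I - 2e = F^-T F^-1
    a00 = 1.0 - 2.0 * g00 + g00 * g00 + g10 * g10
    a11 = 1.0 - 2.0 * g11 + g01 * g01 + g11 * g11
    a01 = -(g01 + g10) + g00 * g01 + g10 * g11
    detA = a00 * a11 - a01 * a01
    if np.any(detA <= 0.0) or np.any(a00 + a11 <= 0.0):
        raise DeformationError("inadmissible deformation: det(I - 2e) <= 0")
    inv_det = 1.0 / detA
    B00 = a11 * inv_det
    B11 = a00 * inv_det
    B01 = -a01 * inv_det
    J = 1.0 / np.sqrt(detA)
    trB = B00 + B11 + 1.0
    vol = two_D1 * (J - 1.0)
    devf = two_C1 * J ** (-5.0 / 3.0)
    S00 = vol + devf * (B00 - trB / 3.0) + psi_elem
    S11 = vol + devf * (B11 - trB / 3.0) + psi_elem
    S01 = devf * B01
    r = np.empty_like(u_elem)
    r[:, :, 0] = area[:, None] * (S00[:, None] * grads[:, :, 0] + S01[:, None] * grads[:, :, 1])
    r[:, :, 1] = area[:, None] * (S01[:, None] * grads[:, :, 0] + S11[:, None] * grads[:, :, 1])
    if collect_load:
        load = (area * psi_elem)[:, None, None] * grads
        return r, load
    return r


def _boundary_residual(u_edge, X_edge, rho_edge, psi_edge, spring_const, spring_comp, params,
                       collect_load=False):
    """Boundary-edge residual contributions (k, 2, 2) on the deformed boundary.

    ``spring_comp`` is -1 for traction-free edges, else the displacement
    component (0 = y, 1 = z) the Robin spring acts on; the spring force and
    the traction-stress boundary term are integrated with two-point Gauss on
    the current edge, with the collagen concentration interpolated pointwise.
    """
    x = X_edge + u_edge  # (k, 2, 2): edge endpoints, CCW orientation
    d = x[:, 1] - x[:, 0]
    r = np.zeros_like(u_edge)
    load = np.zeros_like(u_edge)
    for s, wq in zip(fem.EDGE_GAUSS_POINTS, fem.EDGE_GAUSS_WEIGHTS):
        phi = np.array([1.0 - s, s])
        u_g = (1.0 - s) * u_edge[:, 0] + s * u_edge[:, 1]
        rho_g = (1.0 - s) * rho_edge[:, 0] + s * rho_edge[:, 1]
        psi_g = (1.0 - s) * psi_edge[:, 0] + s * psi_edge[:, 1]
        # outward normal times ds: for CCW traversal, n ds = (dy, -dx)
        n_ds = np.column_stack([d[:, 1], -d[:, 0]])
        t_psi = psi_g[:, None] * n_ds  # traction-stress boundary term (per unit param)
        t_spr = np.zeros_like(u_g)
        mask = spring_comp >= 0
        comp = np.where(mask, spring_comp, 0)
        ds = np.linalg.norm(d, axis=1)
        t_spr[mask, comp[mask]] = (
            -spring_const[mask] * rho_g[mask] * u_g[mask, comp[mask]] * ds[mask]
        )
        for a in range(2):
            r[:, a] -= wq * phi[a] * (t_psi + t_spr)
            load[:, a] -= wq * phi[a] * t_psi
    if collect_load:
        return r, load
    return r


class _MechanicsContext:
    """Precomputed geometry/fields for one quasi-static mechanics solve."""

    def __init__(self, mesh: TriMesh, M_nodal, rho_nodal, params: ParameterSet):
        self.params = params
        self.tri = mesh.triangles
        self.X = mesh.nodes_ref
        self.n = mesh.n_nodes
        self.X_elem = self.X[self.tri]
        # vertex-rule modulus: E ~ mean of sqrt(rho) over element nodes
        sq = np.sqrt(np.maximum(rho_nodal, 0.0))
        E_elem = params.E_I * sq[self.tri].mean(axis=1)
        self.two_C1 = E_elem / (2.0 * (1.0 + params.nu))
        self.two_D1 = E_elem / (3.0 * (1.0 - 2.0 * params.nu))
        psi_nodal = traction_stress(M_nodal, rho_nodal, params)
        self.psi_elem = psi_nodal[self.tri].mean(axis=1)
        self.bedges = mesh.boundary_edges
        self.btags = mesh.boundary_tags
        self.X_edge = self.X[self.bedges]
        self.rho_edge = rho_nodal[self.bedges]
        self.psi_edge = psi_nodal[self.bedges]
        self.spring_const = np.zeros(len(self.bedges))
        self.spring_comp = np.full(len(self.bedges), -1, dtype=int)
        for tag, const, comp in (("B.I", params.s1, 1), ("B.II", params.s2, 0),
                                 ("B.IV", params.s2, 0)):
            m = self.btags == tag
            self.spring_const[m] = const
            self.spring_comp[m] = comp
        self.psi_scale = 1.0

    def residual(self, u: np.ndarray, collect_load=False):
        ue = u[self.tri]
        psi_e = self.psi_scale * self.psi_elem
        out = _interior_residual(ue, self.X_elem, self.two_C1, self.two_D1, psi_e,
                                 collect_load=collect_load)
        r_el, load_el = out if collect_load else (out, None)
        ub = u[self.bedges]
        outb = _boundary_residual(ub, self.X_edge, self.rho_edge,
                                  self.psi_scale * self.psi_edge, self.spring_const,
                                  self.spring_comp, self.params, collect_load=collect_load)
        r_bd, load_bd = outb if collect_load else (outb, None)
        R = np.zeros((self.n, 2))
        np.add.at(R, self.tri, r_el)
        np.add.at(R, self.bedges, r_bd)
        if collect_load:
            L = np.zeros((self.n, 2))
            np.add.at(L, self.tri, load_el)
            np.add.at(L, self.bedges, load_bd)
            return R.ravel(), L.ravel()
        return R.ravel()

    def tangent(self, u: np.ndarray, h: float) -> sp.csr_matrix:
        """Consistent tangent by central differences of the element/edge residuals."""
        tri, bedges = self.tri, self.bedges
        ue = u[tri]
        ub = u[bedges]
        psi_e = self.psi_scale * self.psi_elem
        psi_b = self.psi_scale * self.psi_edge
        rows, cols, vals = [], [], []

        ke = np.empty((len(tri), 6, 6))
        for d in range(6):
            a, i = divmod(d, 2)
            up = ue.copy(); up[:, a, i] += h
            um = ue.copy(); um[:, a, i] -= h
            rp = _interior_residual(up, self.X_elem, self.two_C1, self.two_D1, psi_e)
            rm = _interior_residual(um, self.X_elem, self.two_C1, self.two_D1, psi_e)
            ke[:, :, d] = ((rp - rm) / (2.0 * h)).reshape(len(tri), 6)
        dofs = (2 * tri[:, :, None] + np.arange(2)[None, None, :]).reshape(len(tri), 6)
        rows.append(np.repeat(dofs, 6, axis=1).ravel())
        cols.append(np.tile(dofs, (1, 6)).ravel())
        vals.append(ke.ravel())

        kb = np.empty((len(bedges), 4, 4))
        for d in range(4):
            a, i = divmod(d, 2)
            up = ub.copy(); up[:, a, i] += h
            um = ub.copy(); um[:, a, i] -= h
            rp = _boundary_residual(up, self.X_edge, self.rho_edge, psi_b,
                                    self.spring_const, self.spring_comp, self.params)
            rm = _boundary_residual(um, self.X_edge, self.rho_edge, psi_b,
                                    self.spring_const, self.spring_comp, self.params)
            kb[:, :, d] = ((rp - rm) / (2.0 * h)).reshape(len(bedges), 4)
        dofs_b = (2 * bedges[:, :, None] + np.arange(2)[None, None, :]).reshape(len(bedges), 4)
        rows.append(np.repeat(dofs_b, 4, axis=1).ravel())
        cols.append(np.tile(dofs_b, (1, 4)).ravel())
        vals.append(kb.ravel())

        n2 = 2 * self.n
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n2, n2),
        )


class MechanicsCache:
    """Reusable tangent factorization for the chord (modified Newton) method.

    The tangent varies slowly across defect-correction iterations and time
    steps, so its LU factorization is reused until the observed contraction
    rate degrades; a fresh consistent tangent is then reassembled.
    """

    def __init__(self) -> None:
        self.lu = None
        self.stale = True


def solve_mechanics(
    mesh: TriMesh,
    M_nodal: np.ndarray,
    rho_nodal: np.ndarray,
    params: ParameterSet,
    options: SolverOptions = SolverOptions(),
    u_init: np.ndarray | None = None,
    cache: MechanicsCache | None = None,
) -> tuple[np.ndarray, int]:
    """Quasi-static finite-strain force balance by damped (modified) Newton.

    Returns the total nodal displacement from the reference configuration
    ``(n, 2)`` and the Newton iteration count.  With no myofibroblasts the
    traction stress vanishes and the exact solution ``u = 0`` is returned
    directly.  On Newton failure the traction load is applied in increments
    (load stepping); persistent failure raises :class:`MechanicsError`.
    """
    ctx = _MechanicsContext(mesh, M_nodal, rho_nodal, params)
    # negligible traction: the solution is u = 0 to far below any field tolerance
    E_scale = float(np.max(2.0 * (1.0 + params.nu) * ctx.two_C1, initial=0.0))
    psi_max = max(np.max(ctx.psi_elem, initial=0.0), np.max(ctx.psi_edge, initial=0.0))
    if psi_max <= 1e-3 * options.tol_mech * max(E_scale, 1e-300):
        return np.zeros((mesh.n_nodes, 2)), 0

    u = np.zeros((mesh.n_nodes, 2)) if u_init is None else u_init.copy()
    cache = cache if cache is not None else MechanicsCache()
    total_newton = 0
    for schedule in ([1.0], [0.25, 0.5, 0.75, 1.0]):
        try:
            uk = u.copy()
            for lam in schedule:
                ctx.psi_scale = lam
                uk, it = _newton(ctx, uk, options, cache)
                total_newton += it
            return uk, total_newton
        except (MechanicsError, DeformationError):
            cache.lu = None
            u = np.zeros_like(u)  # restart load stepping from the reference state
            continue
    raise MechanicsError("mechanics Newton failed even with load stepping")


def _newton(ctx: _MechanicsContext, u: np.ndarray, options: SolverOptions,
            cache: MechanicsCache):
    R, load = ctx.residual(u, collect_load=True)
    # reference force: the traction load, floored at the stiffness scale so
    # the tolerance stays above the roundoff level of the assembled residual
    # when the load vanishes (a floor of E * sqrt(area) resolves displacements
    # to well below 1e-10 cm on any mesh used here)
    E_scale = float(np.max(2.0 * (1.0 + ctx.params.nu) * ctx.two_C1, initial=0.0))
    area_tot = float(np.abs(_signed_areas(ctx.X_elem + u[ctx.tri])).sum())
    f_ref = max(np.linalg.norm(load), E_scale * np.sqrt(area_tot), 1e-300)
    norm = np.linalg.norm(R)
    fresh = False
    for it in range(options.newton_max_iter):
        if norm <= options.tol_mech * f_ref:
            return u, it
        if cache.lu is None:
            cache.lu = spla.splu(ctx.tangent(u, options.fd_step).tocsc())
            fresh = True
        du = cache.lu.solve(-R).reshape(-1, 2)
        lam, accepted = 1.0, False
        while lam > 1e-4:
            try:
                u_try = u + lam * du
                R_try = ctx.residual(u_try)
                n_try = np.linalg.norm(R_try)
            except DeformationError:
                lam *= 0.5
                continue
            if n_try < (1.0 - 0.25 * lam) * norm or n_try <= options.tol_mech * f_ref:
                contraction = n_try / max(norm, 1e-300)
                u, R, norm = u_try, R_try, n_try
                accepted = True
                if contraction > 0.2 and not fresh:
                    cache.lu = None  # stale chord factor: rebuild next iteration
                elif contraction > 0.5 and fresh:
                    fresh = False
                    cache.lu = None  # strong nonlinearity: keep re-assembling
                break
            lam *= 0.5
        if not accepted:
            if not fresh:
                cache.lu = None  # retry this iterate with a consistent tangent
                continue
            raise MechanicsError("line search stalled")
    if norm <= options.tol_mech * f_ref:
        return u, options.newton_max_iter
    raise MechanicsError("Newton did not converge within the iteration budget")


# ---------------------------------------------------------------------------
# constituents: moving-mesh backward-Euler systems with FCT + Patankar
# ---------------------------------------------------------------------------

def assemble_constituent_system(
    x_old: np.ndarray,
    x_new: np.ndarray,
    mesh: TriMesh,
    guess: StateFields,
    params: ParameterSet,
    which: str,
):
    """Build the moving-mesh transport pieces for one constituent.

    Returns a dict with the Galerkin transport operator ``K`` (convention
    ``M dz/dt = K z + source``), the old/new lumped and new consistent mass
    matrices, the Patankar production/destruction fields evaluated at the
    defect-correction iterate ``guess``, and the Dirichlet data.  Collagen
    (``which='rho'``) has no flux: ``K`` is zero and the update is the
    pointwise mass-weighted Patankar formula.
    """
    tri = mesh.triangles
    m_old = fem.lumped_mass(x_old, tri)
    m_new = fem.lumped_mass(x_new, tri)
    g = guess
    if which == "N":
        P, D = patankar_split_fibroblast(g.N, g.M, g.c, params)
    elif which == "M":
        P, D = patankar_split_myofibroblast(g.N, g.M, g.c, params)
    elif which == "c":
        P, D = patankar_split_signal(g.N, g.M, g.c, g.rho, params)
    elif which == "rho":
        P, D = patankar_split_collagen(g.N, g.M, g.c, g.rho, params)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(which)

    out = {"m_old": m_old, "m_new": m_new, "production": np.broadcast_to(P, m_old.shape),
           "destruction": np.broadcast_to(np.asarray(D, dtype=float), m_old.shape)}
    if which == "rho":
        out["K"] = None
        return out

    if which == "c":
        K = -fem.stiffness(x_new, tri, params.D_c)
    else:
        F_elem = (g.N + g.M)[tri].mean(axis=1)
        diff = fem.stiffness(x_new, tri, params.D_F * F_elem)
        grad_c = fem.recover_gradient(x_new, tri, g.c)
        adv = fem.advection_divergence(x_new, tri, params.chi_F * grad_c)
        K = -(diff + adv)
    out["K"] = K.tocsr()
    out["mass_consistent"] = fem.consistent_mass(x_new, tri)

    lateral = np.concatenate([mesh.boundary_nodes("B.II"), mesh.boundary_nodes("B.IV")])
    lateral = np.unique(lateral)
    dval = {"N": params.N_bar, "M": params.M_bar, "c": params.c_bar}[which]
    out["dirichlet_idx"] = lateral
    out["dirichlet_val"] = np.full(lateral.shape, dval)
    return out


def advance_constituents(
    x_old: np.ndarray,
    x_new: np.ndarray,
    mesh: TriMesh,
    state_old: StateFields,
    guess: StateFields,
    params: ParameterSet,
    dt: float,
    edges: np.ndarray,
):
    """One FCT + Patankar backward-Euler update of all four constituents.

    Nonlinear coefficients are evaluated at ``guess`` (the defect-correction
    iterate); the caller re-invokes until self-consistency.  Returns the new
    fields and the worst FCT/linear-solve diagnostics.
    """
    new = {}
    reports: list[FCTReport] = []
    for which in ("N", "M", "c"):
        sysd = assemble_constituent_system(x_old, x_new, mesh, guess, params, which)
        z_new, rep = fct_transport_step(
            edges=edges,
            m_old=sysd["m_old"],
            m_new=sysd["m_new"],
            mass_consistent=sysd["mass_consistent"],
            K=sysd["K"],
            dt=dt,
            z_old=getattr(state_old, which),
            production=sysd["production"],
            destruction=sysd["destruction"],
            dirichlet_idx=sysd["dirichlet_idx"],
            dirichlet_val=sysd["dirichlet_val"],
        )
        new[which] = z_new
        reports.append(rep)
    sysd = assemble_constituent_system(x_old, x_new, mesh, guess, params, "rho")
    m_old, m_new = sysd["m_old"], sysd["m_new"]
    P, D = sysd["production"], sysd["destruction"]
    new["rho"] = (m_old * state_old.rho / dt + m_new * P) / (m_new * (1.0 / dt + D))
    return new, reports


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def adapt_timestep(error_estimate: float, control: StepControl) -> tuple[float, bool]:
    """PI-free step-size controller for the first-order scheme.

    Accept iff the scaled local-truncation-error estimate is below the
    tolerance; the next step size follows
    ``dt * clip(safety * sqrt(tol/est), shrink_min, grow_max)``, clamped to
    ``[dt_min, dt_max]``.  Deterministic.
    """
    if error_estimate < 0:
        raise ValueError("error estimate must be non-negative")
    accept = error_estimate <= control.tol
    if error_estimate == 0.0:
        factor = control.grow_max
    else:
        factor = np.clip(control.safety * np.sqrt(control.tol / error_estimate),
                         control.shrink_min, control.grow_max)
    dt_new = float(np.clip(control.dt * factor, control.dt_min, control.dt_max))
    return dt_new, bool(accept)


def _scaled_error(diff: dict[str, np.ndarray], params: ParameterSet) -> float:
    scales = {"N": params.N_bar, "M": params.N_bar, "c": params.c_w, "rho": params.rho_bar}
    return max(float(np.abs(diff[k]).max() / scales[k]) for k in CONSTITUENTS)


def defect_correction_step(
    mesh: TriMesh,
    state: StateFields,
    prev: StateFields | None,
    dt: float,
    dt_prev: float,
    params: ParameterSet,
    options: SolverOptions,
    edges: np.ndarray,
    u_total: np.ndarray,
    cache: MechanicsCache | None = None,
):
    """Attempt one coupled time step of size ``dt``.

    Returns ``(new_state, new_mesh, u_new, est, report)`` on success; raises
    :class:`StepRejected` if the fixed-point loop, the mechanics solve or the
    mesh motion fails.  ``est`` is the scaled local-truncation-error estimate
    from the two-step predictor (0 on the first step, which has no history).
    """
    x_old = mesh.nodes_cur
    guess = state.copy()
    x_new = x_old.copy()
    u_new = u_total.copy()
    newton_total = 0
    max_res = 0.0
    limited = 0
    fp_it = 0
    converged = False
    for fp_it in range(1, options.max_fp_iter + 1):
        new_fields, reports = advance_constituents(
            x_old, x_new, mesh, state, guess, params, dt, edges
        )
        max_res = max(max_res, max(r.residual for r in reports))
        limited = max(limited, sum(r.n_limited for r in reports))
        try:
            u_new, n_it = solve_mechanics(
                mesh, new_fields["M"], new_fields["rho"], params, options,
                u_init=u_new, cache=cache,
            )
        except MechanicsError as exc:
            raise StepRejected(f"mechanics failure: {exc}") from exc
        newton_total += n_it
        x_next = mesh.nodes_ref + u_new

        diff = {k: new_fields[k] - getattr(guess, k) for k in CONSTITUENTS}
        err = _scaled_error(diff, params)
        err = max(err, float(np.abs(x_next - x_new).max()))  # cm, length scale 1
        guess = StateFields(state.time + dt, **new_fields)
        x_new = x_next
        if err < options.tol_fp:
            converged = True
            break
    if not converged:
        raise StepRejected("defect-correction loop did not converge")
    if max_res > options.tol_residual:
        raise StepRejected(f"linear residual {max_res:.2e} above bound")

    # local truncation error estimate + extrapolation (constituents only)
    est = 0.0
    if prev is not None and dt_prev > 0:
        fac = dt / (dt + dt_prev)
        resid = {}
        for k in CONSTITUENTS:
            z_n = getattr(state, k)
            z_p = getattr(prev, k)
            pred = z_n + dt * (z_n - z_p) / dt_prev
            resid[k] = getattr(guess, k) - pred
        est = fac * _scaled_error(resid, params)
        for k in CONSTITUENTS:
            corrected = getattr(guess, k) - fac * resid[k]
            setattr(guess, k, np.maximum(corrected, 0.0))

    try:
        new_mesh = move_mesh(mesh, x_new - x_old, dt)
    except MeshInversionError as exc:
        raise StepRejected(str(exc)) from exc

    report = SolveReport(
        time=guess.time,
        dt=dt,
        accepted=True,
        fp_iterations=fp_it,
        newton_iterations=newton_total,
        lte_estimate=est,
        max_residual=max_res,
        fct_limited_edges=limited,
        min_field_values={k: float(getattr(guess, k).min()) for k in CONSTITUENTS},
    )
    return guess, new_mesh, u_new, est, report


def save_checkpoint(path, mesh: TriMesh, state: StateFields) -> None:
    """Write mesh + fields to an .npz checkpoint for later restart."""
    np.savez(
        path,
        time=state.time, N=state.N, M=state.M, c=state.c, rho=state.rho,
        nodes_ref=mesh.nodes_ref, nodes_cur=mesh.nodes_cur,
        velocity=mesh.velocity, triangles=mesh.triangles,
        boundary_edges=mesh.boundary_edges,
        boundary_tags=np.asarray(mesh.boundary_tags, dtype="U8"),
    )


def load_checkpoint(path) -> tuple[TriMesh, StateFields]:
    """Inverse of :func:`save_checkpoint`."""
    d = np.load(path, allow_pickle=False)
    mesh = TriMesh(
        nodes_ref=d["nodes_ref"], triangles=d["triangles"],
        boundary_edges=d["boundary_edges"], boundary_tags=d["boundary_tags"].astype(str),
        nodes_cur=d["nodes_cur"], velocity=d["velocity"],
    )
    state = StateFields(float(d["time"]), d["N"], d["M"], d["c"], d["rho"])
    return mesh, state


def simulate(
    mesh: TriMesh,
    params: ParameterSet,
    wound: WoundSpec | None,
    duration: float,
    options: SolverOptions = SolverOptions(),
    store_every: int = 1,
    initial: StateFields | None = None,
) -> SimulationResult:
    """Run the coupled solver from the standard initial conditions.

    ``wound=None`` starts from the unwounded equilibrium (``w == 1``);
    passing ``initial`` (e.g. from :func:`load_checkpoint` together with its
    mesh) restarts from that state instead, and ``duration`` then counts
    from ``initial.time``.  Stores every ``store_every``-th accepted state
    (plus the initial and final states).  Raises :class:`StepRejected` if
    the step size underflows ``options.dt_min``.
    """
    if initial is None:
        fields0 = initial_state(mesh.nodes_ref[:, 0], params, wound)
        state = StateFields(0.0, fields0["N"], fields0["M"], fields0["c"], fields0["rho"])
    else:
        state = initial.copy()
        duration = state.time + duration
    prev: StateFields | None = None
    dt_prev = 0.0
    u_total = mesh.displacement.copy()
    edges = _mesh_edges(mesh.triangles)
    cache = MechanicsCache()

    control = StepControl(
        dt=options.dt_init, tol=options.lte_tol, dt_min=options.dt_min,
        dt_max=options.dt_max, safety=options.safety,
        shrink_min=options.shrink_min, grow_max=options.grow_max,
    )
    times = [state.time]
    states = [state.copy()]
    coords = [mesh.nodes_cur.copy()]
    reports: list[SolveReport] = []
    k_accept = 0
    while state.time < duration - 1e-12:
        dt = min(control.dt, duration - state.time)
        try:
            new_state, new_mesh, u_new, est, rep = defect_correction_step(
                mesh, state, prev, dt, dt_prev, params, options, edges, u_total, cache
            )
        except StepRejected:
            control.n_rejected += 1
            control.dt = max(0.5 * dt, control.dt_min)
            if dt <= control.dt_min * (1 + 1e-12):
                raise
            continue
        dt_next, accept = adapt_timestep(est, dc_replace(control, dt=dt))
        if not accept:
            control.n_rejected += 1
            control.dt = dt_next
            rep.accepted = False
            reports.append(rep)
            if dt_next <= control.dt_min * (1 + 1e-12) and dt <= control.dt_min * (1 + 1e-12):
                raise StepRejected("time step underflow under error control")
            continue
        control.n_accepted += 1
        control.dt = dt_next
        prev, dt_prev = state, dt
        state, mesh, u_total = new_state, new_mesh, u_new
        reports.append(rep)
        k_accept += 1
        if k_accept % store_every == 0 or state.time >= duration - 1e-12:
            times.append(state.time)
            states.append(state.copy())
            coords.append(mesh.nodes_cur.copy())
    return SimulationResult(times=times, states=states, coords=coords, mesh=mesh, reports=reports)


def _mesh_edges(tri: np.ndarray) -> np.ndarray:
    e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)
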