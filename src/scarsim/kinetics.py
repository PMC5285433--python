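"""Pointwise reaction kinetics and constituent fluxes.

All functions are pure, vectorized over numpy arrays, and dimensional
(cells, g, cm, day).  ``F = N + M`` denotes the combined (myo)fibroblast
density.  The signaling molecule ``c`` drives chemotaxis, enhanced division,
fibroblast-to-myofibroblast differentiation and enhanced collagen secretion;
a generic MMP (matrix metalloproteinase) level ``g(F, c, rho)`` mediates the
proteolytic breakdown of both the signal and collagen.

Every reaction rate decomposes as ``production - destruction * z`` with both
parts non-negative (see :func:`patankar_split_*`), which is what allows the
solver's Patankar source-term splitting to preserve positivity for any time
step.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "reaction_fibroblast",
    "reaction_myofibroblast",
    "reaction_signal",
    "reaction_collagen",
    "mmp_level",
    "flux_cells",
    "flux_signal",
    "patankar_split_fibroblast",
    "patankar_split_myofibroblast",
    "patankar_split_signal",
    "patankar_split_collagen",
]


def _check_nonneg(**kwargs):
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be non-negative")


def reaction_fibroblast(N, M, c, params: ParameterSet):
    """Net fibroblast rate: enhanced adjusted-logistic division, differentiation
    into myofibroblasts and apoptosis (cells/(cm^3 day))."""
    _check_nonneg(N=N, M=M, c=c)
    N = np.asarray(N, dtype=float)
    F = N + M
    division = (
        params.r_F
        * (1.0 + params.r_F_max * c / (params.a_c_I + c))
        * (1.0 - params.kappa_F * F)
        * N ** (1.0 + params.p)
    )
    return division - params.k_F * c * N - params.delta_N * N


def reaction_myofibroblast(N, M, c, params: ParameterSet):
    """Net myofibroblast rate: signal-gated division, differentiation influx
    from fibroblasts and apoptosis (cells/(cm^3 day))."""
    _check_nonneg(N=N, M=M, c=c)
    M = np.asarray(M, dtype=float)
    F = N + M
    division = (
        params.r_F
        * ((1.0 + params.r_F_max) * c / (params.a_c_I + c))
        * (1.0 - params.kappa_F * F)
        * M ** (1.0 + params.p)
    )
    return division + params.k_F * c * N - params.delta_M * M


def mmp_level(F, c, rho, params: ParameterSet):
    """Generic MMP concentration proxy ``F rho / (1 + a_c_III c)``.

    Produced by (myo)fibroblasts in proportion to the collagen substrate and
    inhibited by the signaling molecule (cells g/cm^6)."""
    _check_nonneg(F=F, c=c, rho=rho)
    return np.asarray(F, dtype=float) * rho / (1.0 + params.a_c_III * c)


def reaction_signal(N, M, c, rho, params: ParameterSet):
    """Net signaling-molecule rate: receptor-saturated secretion by both cell
    types minus MMP-mediated proteolysis (g/(cm^3 day))."""
    _check_nonneg(N=N, M=M, c=c, rho=rho)
    c = np.asarray(c, dtype=float)
    secretion = params.k_c * (N + params.eta * M) * c / (params.a_c_II + c)
    g = mmp_level(np.asarray(N) + np.asarray(M), c, rho, params)
    return secretion - params.delta_c * g * c


def reaction_collagen(N, M, c, rho, params: ParameterSet):
    """Net collagen rate: signal-enhanced secretion by both cell types minus
    MMP-mediated degradation (g/(cm^3 day))."""
    _check_nonneg(N=N, M=M, c=c, rho=rho)
    rho = np.asarray(rho, dtype=float)
    secretion = (
        params.k_rho
        * (1.0 + params.k_rho_max * c / (params.a_c_IV + c))
        * (np.asarray(N) + params.eta * np.asarray(M))
    )
    g = mmp_level(np.asarray(N) + np.asarray(M), c, rho, params)
    return secretion - params.delta_rho * g * rho


def flux_cells(z, F, grad_z, grad_c, params: ParameterSet):
    """Cell flux ``-D_F F grad(z) + chi_F z grad(c)`` for z in {N, M}.

    Density-dependent Fickian dispersal plus chemotaxis up the signal
    gradient; the transport equation uses ``-div(J)``.  ``grad_*`` arrays have
    the spatial components in the last axis.
    """
    _check_nonneg(z=z, F=F)
    z = np.asarray(z, dtype=float)[..., None]
    F = np.asarray(F, dtype=float)[..., None]
    return -params.D_F * F * np.asarray(grad_z, dtype=float) + params.chi_F * z * np.asarray(
        grad_c, dtype=float
    )


def flux_signal(grad_c, params: ParameterSet):
    """Linear Fickian signal flux ``-D_c grad(c)``."""
    return -params.D_c * np.asarray(grad_c, dtype=float)


# ---------------------------------------------------------------------------
# production/destruction decompositions used by the Patankar splitting
# ---------------------------------------------------------------------------

def patankar_split_fibroblast(N, M, c, params: ParameterSet):
    """Return (P, D) with ``R_N = P - D * N``, ``P, D >= 0``.

    The crowding factor can turn the division term negative when
    ``kappa_F (N + M) > 1``; that part is routed to the destruction
    coefficient so both parts stay non-negative.
    """
    N = np.asarray(N, dtype=float)
    F = N + M
    growth = (
        params.r_F
        * (1.0 + params.r_F_max * c / (params.a_c_I + c))
        * (1.0 - params.kappa_F * F)
        * N ** (1.0 + params.p)
    )
    P = np.maximum(growth, 0.0)
    over = np.where(growth < 0.0, -growth / np.maximum(N, 1e-300), 0.0)
    D = params.k_F * np.asarray(c, dtype=float) + params.delta_N + over
    return P, D


def patankar_split_myofibroblast(N, M, c, params: ParameterSet):
    """Return (P, D) with ``R_M = P - D * M``."""
    M = np.asarray(M, dtype=float)
    F = np.asarray(N) + M
    growth = (
        params.r_F
        * ((1.0 + params.r_F_max) * c / (params.a_c_I + c))
        * (1.0 - params.kappa_F * F)
        * M ** (1.0 + params.p)
    )
    P = np.maximum(growth, 0.0) + params.k_F * np.asarray(c) * np.asarray(N)
    over = np.where(growth < 0.0, -growth / np.maximum(M, 1e-300), 0.0)
    D = params.delta_M + over
    return P, np.asarray(D, dtype=float)


def patankar_split_signal(N, M, c, rho, params: ParameterSet):
    """Return (P, D) with ``R_c = P - D * c``."""
    c = np.asarray(c, dtype=float)
    P = params.k_c * (np.asarray(N) + params.eta * np.asarray(M)) * c / (params.a_c_II + c)
    g = mmp_level(np.asarray(N) + np.asarray(M), c, rho, params)
    D = params.delta_c * g
    return np.asarray(P, dtype=float), np.asarray(D, dtype=float)


def patankar_split_collagen(N, M, c, rho, params: ParameterSet):
    """Return (P, D) with ``R_rho = P - D * rho``."""
    rho = np.asarray(rho, dtype=float)
    P = (
        params.k_rho
        * (1.0 + params.k_rho_max * np.asarray(c) / (params.a_c_IV + np.asarray(c)))
        * (np.asarray(N) + params.eta * np.asarray(M))
    )
    g = mmp_level(np.asarray(N) + np.asarray(M), c, rho, params)
    D = params.delta_rho * g
    return np.asarray(P, dtype=float), np.asarray(D, dtype=float)
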