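"""Finite-strain constitutive relations of the dermal layer.

The dermis is a heterogeneous, isotropic, compressible neo-Hookean solid
whose Young's modulus grows with the collagen concentration,
``E(rho) = E_I * sqrt(rho)``.  The kinematics are Eulerian: from the
displacement gradient ``grad_u = d u / d x`` (current coordinates) the
Almansi strain ``e`` and the left Cauchy-Green tensor ``B = (I - 2 e)^-1``
are formed.  Under plane strain, the in-plane 2x2 block carries the
deformation and the out-of-plane stretch is one, so ``J = sqrt(det B_2d)``.

Myofibroblasts pull isotropically on their surroundings; the resulting
traction stress ``psi = xi * M * rho / (R^2 + rho^2) * I`` enters the force
balance as the body force ``f = div(psi)`` (assembled weakly by the solver).

All functions broadcast over leading axes, so they evaluate per-element
arrays as naturally as single points.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "almansi_strain",
    "left_cauchy_green",
    "cauchy_stress",
    "traction_stress",
    "strain_energy",
    "DeformationError",
]


class DeformationError(ValueError):
    """Raised for kinematically inadmissible displacement gradients."""


def almansi_strain(grad_u: np.ndarray) -> np.ndarray:
    """Eulerian (Almansi) strain ``e = (grad_u + grad_u^T - grad_u^T grad_u)/2``."""
    g = np.asarray(grad_u, dtype=float)
    gT = np.swapaxes(g, -1, -2)
    return 0.5 * (g + gT - gT @ g)


def left_cauchy_green(grad_u: np.ndarray, check: bool = True):
    """In-plane left Cauchy-Green tensor ``B = (I - 2 e)^-1`` and ``J``.

    Returns ``(B2, J)`` where ``B2`` is the in-plane 2x2 block and
    ``J = sqrt(det B2)`` is the volume ratio (the out-of-plane stretch is one
    under plane strain).
    """
    e = almansi_strain(grad_u)
    I2 = np.eye(2)
    A = I2 - 2.0 * e  # = B^-1 = F^-T F^-1, must be SPD
    detA = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    trA = A[..., 0, 0] + A[..., 1, 1]
    if check and (np.any(detA <= 0.0) or np.any(trA <= 0.0)):
        raise DeformationError("inadmissible deformation: det(I - 2e) <= 0")
    inv_det = 1.0 / detA
    B2 = np.empty_like(A)
    B2[..., 0, 0] = A[..., 1, 1] * inv_det
    B2[..., 1, 1] = A[..., 0, 0] * inv_det
    B2[..., 0, 1] = -A[..., 0, 1] * inv_det
    B2[..., 1, 0] = -A[..., 1, 0] * inv_det
    J = 1.0 / np.sqrt(detA)
    return B2, J


def _moduli(rho, params: ParameterSet):
    E = params.E_I * np.sqrt(np.asarray(rho, dtype=float))
    two_C1 = E / (2.0 * (1.0 + params.nu))
    two_D1 = E / (3.0 * (1.0 - 2.0 * params.nu))
    return two_C1, two_D1


def cauchy_stress(grad_u: np.ndarray, rho, params: ParameterSet):
    """Cauchy stress of the compressible neo-Hookean dermis.

    The constitutive law defines ``J sigma``; this function returns ``sigma``
    itself (the force balance is stated in sigma).  Returns ``(sigma2,
    sigma33)``: the in-plane 2x2 block and the out-of-plane normal component
    (computed for completeness, it does no work under plane strain).
    """
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be non-negative")
    B2, J = left_cauchy_green(grad_u)
    two_C1, two_D1 = _moduli(rho, params)
    trB = B2[..., 0, 0] + B2[..., 1, 1] + 1.0  # out-of-plane stretch = 1
    vol = two_D1 * (J - 1.0)
    dev_factor = two_C1 * J ** (-5.0 / 3.0)
    I2 = np.eye(2)
    sigma2 = (
        vol[..., None, None] * I2
        + dev_factor[..., None, None] * (B2 - (trB / 3.0)[..., None, None] * I2)
    )
    sigma33 = vol + dev_factor * (1.0 - trB / 3.0)
    return sigma2, sigma33


def traction_stress(M, rho, params: ParameterSet):
    """Isotropic myofibroblast traction stress magnitude (N/cm^2).

    ``psi = xi * M * rho / (R^2 + rho^2)``; the tensor stress is ``psi * I``.
    Saturates in rho with maximum ``xi * M / (2 R)`` at ``rho = R``.
    """
    if np.any(np.asarray(M) < 0) or np.any(np.asarray(rho) < 0):
        raise ValueError("M and rho must be non-negative")
    rho = np.asarray(rho, dtype=float)
    return params.xi * np.asarray(M, dtype=float) * rho / (params.R_half**2 + rho**2)


def strain_energy(grad_u: np.ndarray, rho, params: ParameterSet):
    """Stored strain energy density ``W = C1 (Ibar1 - 3) + D1 (J - 1)^2``.

    ``Ibar1 = J^(-2/3) tr(B)`` is the isochoric first invariant; W >= 0 for
    admissible deformations and vanishes at zero displacement (J/cm^3 when
    stresses are in N/cm^2).
    """
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be non-negative")
    B2, J = left_cauchy_green(grad_u)
    two_C1, two_D1 = _moduli(rho, params)
    trB = B2[..., 0, 0] + B2[..., 1, 1] + 1.0
    Ibar1 = J ** (-2.0 / 3.0) * trB
    W = 0.5 * two_C1 * (Ibar1 - 3.0) + 0.5 * two_D1 * (J - 1.0) ** 2
    # Ibar1 >= 3 by AM-GM at fixed J; clip the roundoff-negative residue
    return np.maximum(W, 0.0)
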