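"""Computational domain, wound profile, initial conditions and boundary data.

The simulated geometry is an infinitely thin 2D slice of dermis in the
``(Y, Z)`` plane (plane strain): ``-15.96 <= Y <= 15.96`` cm wide and
``-0.15 <= Z <= 0`` cm deep.  Its boundary is tagged counterclockwise:

* ``B.I``   bottom, the subcutaneous interface (spring in z),
* ``B.II``  right lateral edge, adjacent dermis (spring in y),
* ``B.III`` top, the epidermal interface (traction-free),
* ``B.IV``  left lateral edge, adjacent dermis (spring in y).

The wound occupies the centre of the slice through its full depth.  Its
footprint is described by the profile ``w(Y)`` built from a smoothed
Heaviside ramp: ``w = 0`` is completely wounded tissue, ``w = 1`` unwounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import InvalidParameterError, ParameterSet

__all__ = [
    "DomainSpec",
    "WoundSpec",
    "BOUNDARY_TAGS",
    "smooth_heaviside",
    "wound_profile",
    "initial_state",
    "boundary_data",
]

BOUNDARY_TAGS = ("B.I", "B.II", "B.III", "B.IV")


@dataclass(frozen=True)
class DomainSpec:
    """The rectangular dermal slice in reference (Lagrangian) coordinates."""

    y_min: float = -15.96
    y_max: float = 15.96
    z_min: float = -0.15
    z_max: float = 0.0

    def __post_init__(self) -> None:
        if not (self.y_min < self.y_max and self.z_min < self.z_max):
            raise InvalidParameterError("degenerate domain extents")

    @property
    def width(self) -> float:
        return self.y_max - self.y_min

    @property
    def thickness(self) -> float:
        return self.z_max - self.z_min


@dataclass(frozen=True)
class WoundSpec:
    """Wound footprint: boundary steepness and half-width in cm."""

    steepness: float = 2.0    # c^I
    half_width: float = 4.0   # c^II

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise InvalidParameterError("wound steepness must be positive")
        if self.half_width < 0:
            raise InvalidParameterError("wound half-width must be non-negative")

    @classmethod
    def from_parameters(cls, params: ParameterSet) -> "WoundSpec":
        return cls(steepness=params.c_I_shape, half_width=params.c_II_shape)


def smooth_heaviside(x, a: float, b: float):
    """Piecewise sine ramp from 0 (x < b-a) to 1 (x > b+a), value 1/2 at x=b."""
    if a <= 0:
        raise InvalidParameterError("ramp half-width a must be positive")
    x = np.asarray(x, dtype=float)
    ramp = 0.5 * (1.0 + np.sin((x - b) * np.pi / (2.0 * a)))
    out = np.where(x < b - a, 0.0, np.where(x > b + a, 1.0, ramp))
    return out if out.ndim else float(out)


def wound_profile(Y, wound: WoundSpec):
    """Wound indicator ``w(Y) in [0, 1]``: 0 fully wounded, 1 unwounded.

    ``w = 1 - (1 - H_s(Y, cI, cII)) * H_s(Y, cI, -cII)``; even in Y, equal to
    1 wherever ``|Y| >= cII + cI``.
    """
    a, b = wound.steepness, wound.half_width
    scalar = np.ndim(Y) == 0
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    out = 1.0 - (1.0 - smooth_heaviside(Y, a, b)) * smooth_heaviside(Y, a, -b)
    return float(out[0]) if scalar else out


def initial_state(Y, params: ParameterSet, wound: WoundSpec | None = None):
    """Nodal fields at t = 0 from reference Y-coordinates.

    Returns a dict with ``N``, ``M``, ``c``, ``rho`` arrays.  Inside the wound
    (w = 0): ``N = N_w * N_bar``, ``rho = rho_w * rho_bar``, ``c = c_w``; in
    the far field the unwounded equilibrium.  ``M = M_bar = 0`` everywhere, so
    the traction body force and hence the initial displacement vanish.
    Pass ``wound=None`` for the unwounded (no-wound) state ``w == 1``.
    """
    Y = np.asarray(Y, dtype=float)
    w = wound_profile(Y, wound) if wound is not None else np.ones_like(Y)
    return {
        "N": (params.N_w + (1.0 - params.N_w) * w) * params.N_bar,
        "M": np.full_like(Y, params.M_bar),
        "c": (1.0 - w) * params.c_w,
        "rho": (params.rho_w + (1.0 - params.rho_w) * w) * params.rho_bar,
    }


def boundary_data(tag: str, params: ParameterSet) -> dict:
    """Constraint descriptor for one boundary segment.

    Constituents: Dirichlet ``N = N_bar, M = M_bar, c = c_bar`` on the lateral
    edges B.II/B.IV; natural zero-flux on B.I/B.III.  Collagen has no flux
    term and therefore no boundary condition anywhere.  Mechanics: spring
    traction ``(0, -s1 rho u_z)`` on B.I, ``(-s2 rho u_y, 0)`` on B.II/B.IV,
    traction-free B.III; springs act on the deformed boundary with rho
    evaluated pointwise.
    """
    if tag not in BOUNDARY_TAGS:
        raise ValueError(f"unknown boundary tag {tag!r}")
    if tag in ("B.II", "B.IV"):
        return {
            "constituents": {
                "type": "dirichlet",
                "values": {"N": params.N_bar, "M": params.M_bar, "c": params.c_bar},
            },
            "mechanics": {"type": "spring", "direction": "y", "constant": params.s2},
        }
    if tag == "B.I":
        return {
            "constituents": {"type": "no_flux"},
            "mechanics": {"type": "spring", "direction": "z", "constant": params.s1},
        }
    return {  # B.III
        "constituents": {"type": "no_flux"},
        "mechanics": {"type": "free"},
    }
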