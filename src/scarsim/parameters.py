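"""Model constants, derived equilibrium parameters and non-dimensional scales.

The model describes the healing dermis through four constituents — fibroblasts
``N`` (cells/cm^3), myofibroblasts ``M`` (cells/cm^3), a generic signaling
molecule ``c`` (g/cm^3, a stand-in for growth factors such as TGF-beta/PDGF)
and collagen ``rho`` (g/cm^3) — mechanically coupled to a compressible
neo-Hookean force balance.  Every constant of the governing equations lives in
:class:`ParameterSet`; all values default to the published estimation table for
human dermis.

Two parameters are *necessary consequences* of the others: the growth-law
exponent ``p`` must make the unwounded fibroblast density ``N_bar`` a steady
state of the adjusted logistic growth law, and the collagen secretion rate
``k_rho`` must balance proteolytic degradation at the unwounded collagen
concentration ``rho_bar``.  They are recomputed at construction time
(:func:`derive_p`, :func:`derive_k_rho`) rather than read from the table, with
a consistency warning if the recomputed value drifts more than 2% from the
printed two-digit value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterSet",
    "ScaleSet",
    "derive_p",
    "derive_k_rho",
    "nondimensionalize",
    "redimensionalize",
    "load_parameters",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter value violates its physical admissibility range."""


def derive_p(r_F: float, kappa_F: float, delta_N: float, N_bar: float) -> float:
    """Growth-law exponent forced by the unwounded fibroblast equilibrium.

    The fibroblast kinetics use an adjusted logistic law ``r_F (1 - kappa_F F)
    N^(1+p)``.  Requiring a zero net rate at the unwounded state
    ``(N, M, c) = (N_bar, 0, 0)`` gives

        r_F * (1 - kappa_F * N_bar) * N_bar**p = delta_N

    hence ``p = ln(delta_N / (r_F (1 - kappa_F N_bar))) / ln(N_bar)``.
    """
    if r_F <= 0 or delta_N <= 0 or N_bar <= 0:
        raise InvalidParameterError("r_F, delta_N and N_bar must be positive")
    crowd = 1.0 - kappa_F * N_bar
    if not 0.0 < crowd:
        raise InvalidParameterError("require kappa_F * N_bar < 1")
    if N_bar == 1.0:
        raise InvalidParameterError("N_bar = 1 makes the exponent indeterminate")
    arg = delta_N / (r_F * crowd)
    if arg <= 0:
        raise InvalidParameterError("non-positive logarithm argument")
    return math.log(arg) / math.log(N_bar)


def derive_k_rho(delta_rho: float, rho_bar: float) -> float:
    """Collagen secretion rate forced by the unwounded collagen equilibrium.

    At the unwounded state (``c = 0``, ``M = 0``) the collagen kinetics reduce
    to ``k_rho * N - delta_rho * N * rho_bar * rho_bar`` for any fibroblast
    density ``N``, so equilibrium requires ``k_rho = delta_rho * rho_bar**2``.
    """
    if delta_rho <= 0 or rho_bar <= 0:
        raise InvalidParameterError("delta_rho and rho_bar must be positive")
    return delta_rho * rho_bar**2


# printed two-significant-figure values used only for the consistency warning
_PRINTED_P = -0.42
_PRINTED_K_RHO = 6e-8


@dataclass(frozen=True)
class ParameterSet:
    """All model constants (dimensional, cm / g / cells / day / N units).

    Defaults reproduce the published parameter table for human dermis.  The
    derived constants ``p`` and ``k_rho`` are recomputed from the others at
    construction; pass explicit values only to override that behaviour.
    """

    # mechanics
    E_I: float = 32.0          # Young-modulus prefactor, N/(g cm)^(1/2)
    nu: float = 0.49           # Poisson ratio
    xi: float = 2e-3           # traction per unit cell density & collagen, N g/(cells cm^2)
    R_half: float = 3e-1       # traction saturation constant, g/cm^3
    # cell transport
    D_F: float = 1e-7          # (myo)fibroblast motility, cm^5/(cells day)
    chi_F: float = 2e-3        # chemotaxis coefficient, cm^5/(g day)
    # fibroblast kinetics
    r_F: float = 9.24e-1       # division rate, cm^(3p)/(cells^p day)
    r_F_max: float = 2.0       # division enhancement factor
    a_c_I: float = 1e-8        # half-max signal level for division enhancement, g/cm^3
    kappa_F: float = 1e-6      # crowding coefficient, cm^3/cells
    k_F: float = 5.4e6         # differentiation rate, cm^3/(g day)
    delta_N: float = 2e-2      # fibroblast apoptosis rate, /day
    delta_M: float = 6e-2      # myofibroblast apoptosis rate, /day (free, (2-60)e-3)
    # signaling molecule
    D_c: float = 2.9e-3        # signal diffusion, cm^2/day
    k_c: float = 4e-13         # max net secretion rate, g/(cells day)
    eta: float = 2.0           # myofibroblast-to-fibroblast secretion ratio
    a_c_II: float = 1e-8       # half-max signal level for secretion, g/cm^3
    delta_c: float = 5e-4      # signal breakdown rate, cm^6/(cells g day)
    a_c_III: float = 2e8       # MMP-inhibition constant, cm^3/g
    # collagen
    k_rho_max: float = 10.0    # secretion enhancement factor
    a_c_IV: float = 1e-9       # half-max signal level for secretion enhancement, g/cm^3
    delta_rho: float = 6e-6    # collagen degradation rate, cm^6/(cells g day)
    # equilibria
    N_bar: float = 1e4         # fibroblast equilibrium density, cells/cm^3
    M_bar: float = 0.0         # myofibroblast equilibrium density, cells/cm^3
    c_bar: float = 0.0         # signal equilibrium concentration, g/cm^3
    rho_bar: float = 1e-1      # collagen equilibrium concentration, g/cm^3
    # wound initial fractions / levels
    N_w: float = 2e-1          # initial fibroblast fraction in the wound
    rho_w: float = 2e-1        # initial collagen fraction in the wound
    c_w: float = 1e-8          # initial wound signal concentration, g/cm^3
    # boundary springs
    s1: float = 1e6            # subcutaneous spring constant, N/g
    s2: float = 1e3            # lateral spring constant, N/g
    # wound shape
    c_I_shape: float = 2.0     # wound boundary steepness, cm
    c_II_shape: float = 4.0    # wound half-width, cm
    # derived (recomputed unless given explicitly)
    p: float = field(default=math.nan)
    k_rho: float = field(default=math.nan)

    def __post_init__(self) -> None:
        self._validate()
        if math.isnan(self.p):
            object.__setattr__(
                self, "p", derive_p(self.r_F, self.kappa_F, self.delta_N, self.N_bar)
            )
            if abs(self.p - _PRINTED_P) > 0.02 * abs(_PRINTED_P):
                warnings.warn(
                    f"recomputed p = {self.p:.4g} differs from the printed "
                    f"{_PRINTED_P} by more than 2%",
                    stacklevel=2,
                )
        if math.isnan(self.k_rho):
            object.__setattr__(self, "k_rho", derive_k_rho(self.delta_rho, self.rho_bar))
            if abs(self.k_rho - _PRINTED_K_RHO) > 0.02 * _PRINTED_K_RHO:
                warnings.warn(
                    f"recomputed k_rho = {self.k_rho:.4g} differs from the printed "
                    f"{_PRINTED_K_RHO} by more than 2%",
                    stacklevel=2,
                )

    def _validate(self) -> None:
        nonneg = (
            "E_I", "xi", "R_half", "D_F", "chi_F", "r_F", "r_F_max", "a_c_I",
            "kappa_F", "k_F", "delta_N", "delta_M", "D_c", "k_c", "eta",
            "a_c_II", "delta_c", "a_c_III", "k_rho_max", "a_c_IV", "delta_rho",
            "N_bar", "M_bar", "c_bar", "rho_bar", "c_w", "s1", "s2",
            "c_I_shape", "c_II_shape",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.0 < self.nu < 0.5:
            raise InvalidParameterError("Poisson ratio must satisfy 0 < nu < 0.5")
        if not 0.0 <= self.N_w <= 1.0:
            raise InvalidParameterError("N_w must lie in [0, 1]")
        if not 0.0 <= self.rho_w <= 1.0:
            raise InvalidParameterError("rho_w must lie in [0, 1]")
        if not self.kappa_F * self.N_bar < 1.0:
            raise InvalidParameterError("require kappa_F * N_bar < 1")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields changed (p/k_rho re-derived
        unless supplied explicitly)."""
        derived = {"p", "k_rho"}
        kept = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name not in derived
        }
        kept.update(changes)
        for name in derived - changes.keys():
            kept[name] = math.nan
        return ParameterSet(**kept)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ScaleSet:
    """Characteristic scales of the non-dimensionalization.

    The governing equations are invariant under this rescaling, so the choice
    only affects the numerical representation; correctness is checked by the
    round-trip identity ``redimensionalize(nondimensionalize(x)) == x``.
    """

    length: float = 1.0        # cm
    time: float = 1.0          # day
    density: float = 1e4       # cells/cm^3 (fibroblast equilibrium)
    signal: float = 1e-8       # g/cm^3 (initial wound signal level)
    collagen: float = 1e-1     # g/cm^3 (collagen equilibrium)
    stress: float = 32.0 * math.sqrt(1e-1)  # N/cm^2, E_I * sqrt(rho_bar)

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise InvalidParameterError(f"scale {f.name} must be positive")

    @classmethod
    def from_parameters(cls, params: ParameterSet) -> "ScaleSet":
        return cls(
            length=1.0,
            time=1.0,
            density=params.N_bar,
            signal=params.c_w,
            collagen=params.rho_bar,
            stress=params.E_I * math.sqrt(params.rho_bar),
        )


def _scale_factors(params: ParameterSet, s: ScaleSet) -> dict[str, float]:
    """Dimensional scale of every parameter, as a product of base scales.

    Dividing each dimensional parameter by its factor yields the coefficient
    that multiplies the corresponding term of the governing equations written
    in the scaled variables N/n*, c/c*, rho/rho*, x/L*, t/T*, sigma/sigma*.
    """
    L, T, n, c, r, sg = s.length, s.time, s.density, s.signal, s.collagen, s.stress
    p = params.p
    return {
        # mechanics: sigma scale sg; E(rho) = E_I sqrt(rho) must scale as sg
        "E_I": sg / math.sqrt(r),
        "nu": 1.0,
        "xi": sg * r / n,  # psi = xi*M*rho/(R^2+rho^2) ~ xi*n/r -> sg
        "R_half": r,
        "D_F": L**2 / (n * T),
        "chi_F": L**2 / (c * T),
        "r_F": n ** (-p) / T,
        "r_F_max": 1.0,
        "a_c_I": c,
        "kappa_F": 1.0 / n,
        "k_F": 1.0 / (c * T),
        "delta_N": 1.0 / T,
        "delta_M": 1.0 / T,
        "D_c": L**2 / T,
        "k_c": c / (n * T),
        "eta": 1.0,
        "a_c_II": c,
        "delta_c": 1.0 / (n * r * T),
        "a_c_III": 1.0 / c,
        "k_rho": r / (n * T),
        "k_rho_max": 1.0,
        "a_c_IV": c,
        "delta_rho": 1.0 / (n * r * T),  # R_rho decay ~ delta_rho*(n*r)*r -> r/T
        "N_bar": n,
        "M_bar": n,
        "c_bar": c,
        "rho_bar": r,
        "N_w": 1.0,
        "rho_w": 1.0,
        "c_w": c,
        "s1": sg / (r * L),  # traction s1*rho*u ~ s1*r*L -> sg
        "s2": sg / (r * L),
        "c_I_shape": L,
        "c_II_shape": L,
        "p": 1.0,
    }


def nondimensionalize(params: ParameterSet, scales: ScaleSet) -> dict[str, float]:
    """Map a dimensional :class:`ParameterSet` to dimensionless coefficients."""
    factors = _scale_factors(params, scales)
    out = {}
    for name, fac in factors.items():
        out[name] = getattr(params, name) / fac
    return out

def redimensionalize(dimless: Mapping[str, float], scales: ScaleSet) -> ParameterSet:
    """Inverse of :func:`nondimensionalize` (round trip is the identity)."""
    # factors depend only on p among the parameter values, which is dimensionless
    probe = ParameterSet(p=dimless["p"], k_rho=math.nan)
    factors = _scale_factors(probe, scales)
    vals = {name: dimless[name] * fac for name, fac in factors.items()}
    return ParameterSet(**vals)


def load_parameters(source: str | Mapping[str, Any] | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML/JSON file path or mapping.

    Keys are named after the table symbols (``delta_M``, ``a_c_I``, ...);
    omitted keys keep their defaults, and ``p``/``k_rho`` are re-derived.
    """
    if source is None:
        return ParameterSet()
    if isinstance(source, str):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    known = {f.name for f in fields(ParameterSet)}
    unknown = set(data) - known
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return ParameterSet(**{k: float(v) for k, v in data.items()})
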