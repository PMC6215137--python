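"""Mapping between physical material parameters and reduced simulation units.

The simulation itself is formulated entirely in reduced units: the thermal
energy ``kT`` is the unit of energy, the unit of length is fixed by assigning
the magnetic nanoparticle a reduced diameter ``a_red`` (default 1.2), and the
magnetic couplings enter through two dimensionless groups,

* ``lambda_dd`` — the dipolar coupling constant, the contact dipole-dipole
  energy of two co-linear particles relative to ``kT``:
  ``lambda = mu0 * mu^2 / (4 pi a^3 kT)`` (SI point-dipole convention), and
* ``xi`` — the Langevin argument, the Zeeman energy relative to ``kT``:
  ``xi = mu0 * mu * H / kT``.

This module converts material data (saturation magnetisation, particle size,
temperature, viscosity, surface tension) into those groups and provides the
order-of-magnitude consistency checks that justify treating the membrane
interfaces as area-conserving, effectively impermeable walls.

Note on the 4*pi convention: the dipolar coupling for single-domain maghemite
(Ms ~ 400 kA/m, a ~ 10 nm, room temperature) is of order one only when the
contact energy carries the SI factor 1/(4 pi); this module uses that
convention throughout, and the reduced force field consumes ``lambda_dd``
consistently, so simulated behaviour is independent of the bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MU0",
    "KB",
    "MaterialParams",
    "ReducedParams",
    "LengthScale",
    "SurfaceTensionRatios",
    "dipole_moment",
    "lambda_from_material",
    "xi_coefficient",
    "xi_from_field",
    "unit_of_length",
    "surface_tension_ratios",
    "membrane_thickness_physical",
    "shell_thickness_ratio",
    "round_to_sig",
    "nearest_power_of_ten",
]

#: Vacuum permeability, SI (exact pre-2019 value; difference is irrelevant here).
MU0 = 4.0e-7 * math.pi
#: Boltzmann constant, J/K (exact, SI 2019).
KB = 1.380649e-23


@dataclass(frozen=True)
class MaterialParams:
    """Physical parameters of the magnetic particles and their environment.

    Attributes
    ----------
    Ms : float
        Saturation magnetisation of the particle material, A/m.
    a_phys : float
        Particle diameter, m.
    T : float
        Absolute temperature, K.
    eta : float
        Dynamic viscosity of the intra-membrane carrier fluid, Pa*s.
    sigma_s : float
        Surface tension of the membrane interfaces, N/m.
    """

    Ms: float = 4.0e5
    a_phys: float = 1.0e-8
    T: float = 300.0
    eta: float = 1.0e-3
    sigma_s: float = 2.0e-2

    def __post_init__(self) -> None:
        for name in ("Ms", "a_phys", "T", "eta", "sigma_s"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"MaterialParams.{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless simulation parameters.

    ``kT`` is the unit of energy and is identically 1 in reduced units;
    it is kept as a field so the object is self-describing.
    """

    lambda_dd: float = 1.0
    xi: float = 0.0
    length_unit: float = 1.0e-8 / 1.2  # m per reduced length
    a_red: float = 1.2
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_dd < 0.0:
            raise ValueError(f"lambda_dd must be >= 0, got {self.lambda_dd}")
        if self.xi < 0.0:
            raise ValueError(f"xi must be >= 0, got {self.xi}")
        if not self.length_unit > 0.0:
            raise ValueError(f"length_unit must be > 0, got {self.length_unit}")


def dipole_moment(Ms: float, a_phys: float) -> float:
    """Magnetic moment of a uniformly magnetised spherical particle, A*m^2.

    ``mu = Ms * (pi/6) * a^3`` — saturation magnetisation times particle
    volume. For maghemite (Ms = 400 kA/m) at a = 10 nm this is ~2e-19.
    """
    if not a_phys > 0.0:
        raise ValueError(f"particle diameter must be > 0, got {a_phys}")
    if Ms < 0.0:
        raise ValueError(f"saturation magnetisation must be >= 0, got {Ms}")
    return Ms * (math.pi / 6.0) * a_phys**3


def lambda_from_material(p: MaterialParams) -> float:
    """Dipolar coupling constant ``lambda = mu0 mu^2 / (4 pi a^3 kB T)``.

    Ratio of the contact head-to-tail dipole-dipole energy scale to thermal
    energy. Scales as Ms^2 and a^3. ~1 for 10 nm maghemite at room
    temperature.
    """
    if not p.T > 0.0:
        raise ValueError(f"temperature must be > 0, got {p.T}")
    mu = dipole_moment(p.Ms, p.a_phys)
    return MU0 * mu**2 / (4.0 * math.pi * p.a_phys**3 * KB * p.T)


def xi_coefficient(moment: float, T: float) -> float:
    """Proportionality coefficient between field H (A/m) and xi: ``mu0*mu/(kB*T)``, m/A."""
    if not T > 0.0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return MU0 * moment / (KB * T)


def xi_from_field(H: float, moment: float, T: float) -> float:
    """Langevin argument ``xi = mu0 * mu * H / (kB * T)`` (dimensionless).

    Linear in H; ~5 at the reference field H = 80 kA/m for a 10 nm
    maghemite particle at room temperature.
    """
    if H < 0.0:
        raise ValueError(f"field strength must be >= 0, got {H}")
    return xi_coefficient(moment, T) * H


@dataclass(frozen=True)
class LengthScale:
    """Conversion between reduced and physical lengths."""

    unit: float  # m per reduced length

    def to_physical(self, reduced: float) -> float:
        return reduced * self.unit

    def to_reduced(self, physical: float) -> float:
        return physical / self.unit


def unit_of_length(a_phys: float, a_red: float = 1.2) -> LengthScale:
    """Physical length of one reduced unit: ``a_phys / a_red``.

    With a 10 nm particle of reduced diameter 1.2 the unit is ~8.3 nm, so a
    reduced outer diameter of 24 corresponds to a ~200 nm polymersome.
    """
    if not a_red > 0.0:
        raise ValueError(f"reduced diameter must be > 0, got {a_red}")
    if not a_phys > 0.0:
        raise ValueError(f"physical diameter must be > 0, got {a_phys}")
    return LengthScale(unit=a_phys / a_red)


@dataclass(frozen=True)
class SurfaceTensionRatios:
    """Raw dimensionless ratios plus nearest-power-of-ten helpers."""

    thermal_ratio: float
    magnetic_ratio: float

    @property
    def thermal_order(self) -> int:
        return nearest_power_of_ten(self.thermal_ratio)

    @property
    def magnetic_order(self) -> int:
        return nearest_power_of_ten(self.magnetic_ratio)


def surface_tension_ratios(p: MaterialParams) -> SurfaceTensionRatios:
    """Surface tension vs thermal and magnetic energy scales.

    ``thermal_ratio = sigma_s a^2 / kT`` compares the work of opening a
    particle-sized hole in the interface with thermal energy (~1e3 for
    typical polymersome walls: a thermally agitated particle cannot deform
    the interfaces). ``magnetic_ratio = sigma_s a^5 / (mu0 mu^2)`` compares
    it with the pair contact magnetic energy; both >> 1 justify treating the
    interfaces as area-conserving.
    """
    mu = dipole_moment(p.Ms, p.a_phys)
    thermal = p.sigma_s * p.a_phys**2 / (KB * p.T)
    magnetic = p.sigma_s * p.a_phys**5 / (MU0 * mu**2) if mu > 0 else 0.0
    return SurfaceTensionRatios(thermal_ratio=thermal, magnetic_ratio=magnetic)


def membrane_thickness_physical(Dout: float, Din: float, scale: LengthScale) -> float:
    """Physical distance between the two polar interfaces, (Dout-Din)/2 in metres."""
    return scale.to_physical((Dout - Din) / 2.0)


def shell_thickness_ratio(Dout: float, Din: float) -> float:
    """Shell thickness relative to overall size: ``(Dout - Din) / (2 Dout)``.

    1/6 for the default geometry (24, 16); controls how strongly the vesicle
    can elongate — thinner shells deform more.
    """
    if not Dout > Din > 0.0:
        raise ValueError(f"need Dout > Din > 0, got Dout={Dout}, Din={Din}")
    return (Dout - Din) / (2.0 * Dout)


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0.0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


def nearest_power_of_ten(x: float) -> int:
    """Exponent n of the power of ten nearest to ``|x|`` on a log scale (0 -> 0)."""
    if x == 0.0:
        return 0
    return int(round(math.log10(abs(x))))
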