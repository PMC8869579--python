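"""Material models for shear-horizontal acoustic transmission lines.

Every layer of a Love-wave guide is described, for the shear polarization,
by a characteristic acoustic impedance ``Zc`` (shear stress over particle
velocity for a plane shear wave) and a complex propagation wavenumber ``k``.
Both follow from the density ``rho`` and a complex shear modulus

    mu_c = mu + j*omega*eta

which covers the three rheological kinds used here in a single expression:

* rigid (elastic) solid:  ``mu_c = mu``          -> real Zc, real k
* Newtonian liquid:       ``mu_c = j*omega*eta`` -> Zc = sqrt(j*omega*rho*eta)
* viscoelastic solid:     ``mu_c = mu + j*omega*eta`` (Voigt-type parallel
  circuit: compliance C, loss conductance G, mass L per unit length)

Sign conventions: time dependence ``exp(+j*omega*t)``, propagation
``exp(-j*k*x)``.  Square roots are taken on the principal branch, which has
``Re >= 0``; for passive media this yields ``Re(Zc) >= 0`` and an amplitude
that decays along the propagation direction (``Im(k) <= 0``).

The module also provides glycerol-water mixture correlations (viscosity and
density at a given temperature) used to design calibration liquids, plus a
small named-material library backed by a JSON data file.
"""

from __future__ import annotations

import cmath
import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "MaterialKind",
    "Material",
    "ViscoelasticCircuit",
    "GlycerolSolution",
    "characteristic_impedance",
    "propagation_factor",
    "complex_shear_modulus",
    "viscoelastic_circuit",
    "glycerol_properties",
    "solve_mass_fraction",
    "water_viscosity",
    "water_density",
    "glycerol_viscosity",
    "glycerol_density",
    "load_material",
    "available_materials",
    "cp_to_pa_s",
    "pa_s_to_cp",
]

CP_PER_PA_S = 1000.0


def cp_to_pa_s(eta_cp: float) -> float:
    """Convert a viscosity in centipoise to Pa*s (1 cP = 1e-3 Pa*s)."""
    return eta_cp / CP_PER_PA_S


def pa_s_to_cp(eta: float) -> float:
    """Convert a viscosity in Pa*s to centipoise."""
    return eta * CP_PER_PA_S


class MaterialKind(str, enum.Enum):
    """Rheological classification of a layer medium."""

    RIGID_SOLID = "rigid_solid"
    VISCOELASTIC_SOLID = "viscoelastic_solid"
    NEWTONIAN_LIQUID = "newtonian_liquid"
    VACUUM = "vacuum"


@dataclass(frozen=True)
class Material:
    """An isotropic, homogeneous medium for SH-wave transmission-line modelling.

    Parameters
    ----------
    name
        Free-form label ("SU8", "water_25C", ...).
    kind
        Rheological kind; decides which of ``shear_modulus`` / ``viscosity``
        must be supplied.
    density
        Mass density in kg/m^3.  Must be positive except for vacuum.
    shear_modulus
        Elastic shear modulus ``mu`` in Pa (rigid and viscoelastic solids).
    viscosity
        Dynamic viscosity ``eta`` in Pa*s (Newtonian liquids and
        viscoelastic solids).
    """

    name: str
    kind: MaterialKind
    density: float = 0.0
    shear_modulus: Optional[float] = None
    viscosity: Optional[float] = None

    def __post_init__(self) -> None:
        kind = MaterialKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is MaterialKind.VACUUM:
            if self.density != 0.0:
                raise ValueError("vacuum must have zero density")
            return
        if self.density <= 0.0:
            raise ValueError(f"{self.name}: density must be > 0, got {self.density}")
        if kind in (MaterialKind.RIGID_SOLID, MaterialKind.VISCOELASTIC_SOLID):
            if self.shear_modulus is None or self.shear_modulus <= 0.0:
                raise ValueError(f"{self.name}: {kind.value} requires shear_modulus > 0")
        if kind in (MaterialKind.NEWTONIAN_LIQUID, MaterialKind.VISCOELASTIC_SOLID):
            if self.viscosity is None or self.viscosity < 0.0:
                raise ValueError(f"{self.name}: {kind.value} requires viscosity >= 0")

    @property
    def shear_velocity(self) -> float:
        """Low-loss shear wave speed ``sqrt(mu/rho)`` in m/s.

        For a Newtonian liquid there is no elastic shear speed; ``0.0`` is
        returned (the liquid never bounds a guided mode from below).
        """
        if self.kind in (MaterialKind.RIGID_SOLID, MaterialKind.VISCOELASTIC_SOLID):
            assert self.shear_modulus is not None
            return math.sqrt(self.shear_modulus / self.density)
        return 0.0

    def lossless(self) -> "Material":
        """Elastic twin of this material: viscosity dropped, liquids -> vacuum.

        Used to locate dispersion roots on the real axis before switching
        losses back on.
        """
        if self.kind is MaterialKind.VISCOELASTIC_SOLID:
            return Material(self.name + "_elastic", MaterialKind.RIGID_SOLID,
                            self.density, self.shear_modulus)
        if self.kind is MaterialKind.NEWTONIAN_LIQUID:
            return VACUUM
        return self


VACUUM = Material("vacuum", MaterialKind.VACUUM)


def complex_shear_modulus(material: Material, omega: float) -> complex:
    """Complex shear modulus ``mu + j*omega*eta`` in Pa at angular frequency omega."""
    if material.kind is MaterialKind.VACUUM:
        return 0.0 + 0.0j
    mu = material.shear_modulus or 0.0
    eta = material.viscosity or 0.0
    return mu + 1j * omega * eta


def _require_positive_omega(omega: float) -> None:
    if omega <= 0.0:
        raise ValueError(f"angular frequency must be > 0, got {omega}")


def characteristic_impedance(material: Material, omega: float) -> complex:
    """Characteristic shear acoustic impedance ``Zc = sqrt(rho * mu_c)`` in Pa*s/m.

    Rigid solid: ``sqrt(rho*mu)`` (purely real).  Newtonian liquid:
    ``sqrt(j*omega*rho*eta)``.  Viscoelastic solid: the parallel-circuit form
    ``sqrt(j*omega*L / (G + j*omega*C))`` — algebraically equal to
    ``sqrt(rho*(mu + j*omega*eta))``.  The principal square root keeps
    ``Re(Zc) >= 0`` (passive medium).  Vacuum returns exactly 0.
    """
    _require_positive_omega(omega)
    if material.kind is MaterialKind.VACUUM:
        return 0.0 + 0.0j
    return cmath.sqrt(material.density * complex_shear_modulus(material, omega))


def propagation_factor(material: Material, omega: float) -> complex:
    """Complex propagation wavenumber ``k = omega * sqrt(rho / mu_c)`` in 1/m.

    Rigid solid: real ``omega/sqrt(mu/rho)``.  Lossy media: the principal
    branch gives ``Re(k) > 0`` and ``Im(k) < 0`` so ``exp(-j*k*x)`` decays in
    the direction of travel.  A Newtonian liquid satisfies
    ``|Re k| = |Im k|`` (45-degree loss angle).
    """
    _require_positive_omega(omega)
    if material.kind is MaterialKind.VACUUM:
        raise ValueError("vacuum supports no shear wave; propagation factor undefined")
    mu_c = complex_shear_modulus(material, omega)
    if mu_c == 0:
        raise ValueError(f"{material.name}: zero shear stiffness and viscosity")
    return omega * cmath.sqrt(material.density / mu_c)


@dataclass(frozen=True)
class ViscoelasticCircuit:
    """Voigt-type parallel circuit equivalent of a viscoelastic solid.

    Per unit length of the acoustic line: shunt compliance ``C`` (1/Pa),
    shunt loss conductance ``G`` (1/(Pa*s)) and series mass ``L = rho``
    (kg/m^3), evaluated at angular frequency ``omega``.
    """

    C: float
    G: float
    L: float
    omega: float


def viscoelastic_circuit(mu: float, eta: float, rho: float, omega: float) -> ViscoelasticCircuit:
    """Parallel-circuit parameters of a viscoelastic solid.

    C = mu / (omega^2 eta^2 + mu^2),  G = eta omega^2 / (omega^2 eta^2 + mu^2),
    L = rho.  Equivalent to the admittance ``Y = j*omega / (mu + j*omega*eta)``;
    the loss tangent identity ``G/(omega*C) = omega*eta/mu`` follows.
    """
    _require_positive_omega(omega)
    if mu < 0 or eta < 0:
        raise ValueError("mu and eta must be non-negative")
    if mu == 0.0 and eta == 0.0:
        raise ValueError("mu and eta cannot both be zero (degenerate circuit)")
    denom = (omega * eta) ** 2 + mu**2
    return ViscoelasticCircuit(C=mu / denom, G=eta * omega**2 / denom, L=rho, omega=omega)


# ---------------------------------------------------------------------------
# Glycerol-water calibration liquids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycerolSolution:
    """Properties of an aqueous glycerol solution at a given temperature.

    ``mass_fraction`` is the glycerol w/w fraction in [0, 1], ``temperature``
    in degrees Celsius, ``viscosity`` in Pa*s, ``density`` in kg/m^3.
    """

    mass_fraction: float
    temperature: float
    viscosity: float
    density: float

    @property
    def viscosity_cp(self) -> float:
        return pa_s_to_cp(self.viscosity)

    def as_material(self, name: Optional[str] = None) -> Material:
        """Newtonian-liquid Material with this solution's density and viscosity."""
        label = name or f"glycerol_w{self.mass_fraction:.4f}_{self.temperature:g}C"
        return Material(label, MaterialKind.NEWTONIAN_LIQUID,
                        density=self.density, viscosity=self.viscosity)


def water_viscosity(temperature: float) -> float:
    """Viscosity of pure water in Pa*s (Cheng 2008 fit, 0-100 C)."""
    t = temperature
    return 1.790e-3 * math.exp((-1230.0 - t) * t / (36100.0 + 360.0 * t))


def glycerol_viscosity(temperature: float) -> float:
    """Viscosity of pure glycerol in Pa*s (Cheng 2008 fit, 0-100 C)."""
    t = temperature
    return 12.100 * math.exp((-1233.0 + t) * t / (9900.0 + 70.0 * t))


def water_density(temperature: float) -> float:
    """Density of pure water in kg/m^3 (Volk & Kaehler 2018 fit)."""
    return 1000.0 * (1.0 - abs((temperature - 3.98) / 615.0) ** 1.71)


def glycerol_density(temperature: float) -> float:
    """Density of pure glycerol in kg/m^3 (linear fit, Volk & Kaehler 2018)."""
    return 1277.0 - 0.654 * temperature


# Amplitude of the volume-contraction correction of the Volk & Kaehler (2018)
# mixture-density model; peak contraction ~1% near w = 0.5.
_CONTRACTION_AMPLITUDE = 0.0097


def _check_w_T(mass_fraction: float, temperature: float) -> None:
    if not 0.0 <= mass_fraction <= 1.0:
        raise ValueError(f"glycerol mass fraction must be in [0, 1], got {mass_fraction}")
    if not 0.0 <= temperature <= 100.0:
        raise ValueError(f"temperature must be in [0, 100] C, got {temperature}")


def glycerol_properties(mass_fraction: float, temperature: float = 25.0) -> GlycerolSolution:
    """Viscosity and density of a glycerol-water mixture.

    Viscosity follows the Cheng (2008) exponent-blending correlation

        eta = eta_w^alpha * eta_g^(1-alpha),
        alpha = 1 - w + a*b*w*(1-w) / (a*w + b*(1-w)),
        a = 0.705 - 0.0017*T,   b = (4.9 + 0.036*T) * a^2.5.

    Density is volume-additive mixing of the pure components with the
    Volk & Kaehler (2018) contraction correction

        rho = kappa * rho_g*rho_w / (w*rho_w + (1-w)*rho_g),
        kappa = 1 + A * sin(pi * w^1.31)^0.81.
    """
    _check_w_T(mass_fraction, temperature)
    w, t = mass_fraction, temperature
    eta_w = water_viscosity(t)
    eta_g = glycerol_viscosity(t)
    a = 0.705 - 0.0017 * t
    b = (4.9 + 0.036 * t) * a**2.5
    alpha = 1.0 - w + a * b * w * (1.0 - w) / (a * w + b * (1.0 - w))
    eta = eta_w**alpha * eta_g ** (1.0 - alpha)

    rho_w = water_density(t)
    rho_g = glycerol_density(t)
    rho_ideal = rho_g * rho_w / (w * rho_w + (1.0 - w) * rho_g)
    kappa = 1.0 + _CONTRACTION_AMPLITUDE * math.sin(math.pi * w**1.31) ** 0.81
    return GlycerolSolution(mass_fraction=w, temperature=t,
                            viscosity=eta, density=kappa * rho_ideal)


def solve_mass_fraction(target_viscosity: float, temperature: float = 25.0,
                        rtol: float = 1e-6) -> float:
    """Glycerol mass fraction whose mixture viscosity matches ``target_viscosity`` (Pa*s).

    Inverts :func:`glycerol_properties` by bisection (the correlation is
    strictly increasing in w at fixed temperature).  Raises ``ValueError``
    when the target lies outside [water, pure glycerol] at that temperature.
    """
    lo_eta = water_viscosity(temperature)
    hi_eta = glycerol_viscosity(temperature)
    if not lo_eta <= target_viscosity <= hi_eta:
        raise ValueError(
            f"target viscosity {target_viscosity:g} Pa*s outside achievable range "
            f"[{lo_eta:g}, {hi_eta:g}] at {temperature:g} C")
    if target_viscosity == lo_eta:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        eta = glycerol_properties(mid, temperature).viscosity
        if abs(eta - target_viscosity) <= rtol * target_viscosity:
            return mid
        if eta < target_viscosity:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Named material library
# ---------------------------------------------------------------------------

def _library() -> dict:
    text = resources.files("lovewave.data").joinpath("materials.json").read_text()
    return json.loads(text)


def available_materials() -> list[str]:
    """Names available to :func:`load_material`."""
    return sorted(_library().keys())


def load_material(name: str) -> Material:
    """Load a material by name from the packaged library.

    The library covers the reference 30 MHz sensor stack (LiNbO3 36Y-X
    substrate treated as an isotropic rigid solid, Cr/Au metallization,
    SU-8 guiding layer) and the glycerol-water calibration liquids at 25 C.
    """
    lib = _library()
    try:
        entry = dict(lib[name])
    except KeyError:
        raise KeyError(f"unknown material {name!r}; available: {', '.join(sorted(lib))}") from None
    entry.pop("comment", None)
    return Material(name=name, **entry)
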