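"""Reduced units and elastic down-scaling.

Fundamental DPD scales are a length ``r_c`` (the interaction cutoff), a mass
``m`` (one water bead), and an energy ``eps = k_B T0``; the time scale follows
as ``tau = sqrt(m r_c^2 / eps)``.  Because 2D elastic moduli of real shells are
enormous in these units (they scale as r_c^2/eps), all elastic moduli and the
solvent viscosity are multiplied by a factor ``f_scale << 1`` before a
simulation.  This leaves the Foppl-von-Karman number E R0^2/kappa and the
capillary number eta gdot R/mu unchanged, so equilibrium shapes, buckling modes
and flow behaviour are preserved; measured forces and pressures must be divided
by ``f_scale`` on output to recover physical magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

KB = 1.380649e-23  # J/K
RHO_WATER_EXP = 997.0  # kg/m^3
RHO_NUMBER_DEFAULT = 3.0  # beads per r_c^3


def derive_time_scale(r_c: float, mass: float, energy: float) -> float:
    """Time scale tau = sqrt(m r_c^2 / eps) from the other three scales."""
    if r_c <= 0 or mass <= 0 or energy <= 0:
        raise ValueError("fundamental scales must be strictly positive")
    return math.sqrt(mass * r_c * r_c / energy)


def mass_scale(r_c: float, rho_number: float = RHO_NUMBER_DEFAULT,
               rho_physical: float = RHO_WATER_EXP) -> float:
    """Bead mass m = rho_phys * r_c^3 / rho_number so one water bead weighs 1 m."""
    if r_c <= 0 or rho_number <= 0 or rho_physical <= 0:
        raise ValueError("inputs must be positive")
    return rho_physical * r_c ** 3 / rho_number


@dataclass(frozen=True)
class UnitSystem:
    """Fundamental scales: length r_c [m], mass [kg], energy eps=k_B*T0 [J]."""

    r_c: float
    mass: float
    energy: float
    T0: float = 300.0

    def __post_init__(self):
        if min(self.r_c, self.mass, self.energy, self.T0) <= 0:
            raise ValueError("all unit scales must be strictly positive")

    @property
    def tau(self) -> float:
        return derive_time_scale(self.r_c, self.mass, self.energy)

    # conversions: reduced -> physical multiply, physical -> reduced divide
    def to_physical(self, value: float, dimension: str) -> float:
        return value * self._factor(dimension)

    def to_reduced(self, value: float, dimension: str) -> float:
        return value / self._factor(dimension)

    def _factor(self, dimension: str) -> float:
        r, m, e, t = self.r_c, self.mass, self.energy, self.tau
        factors = {
            "length": r,
            "mass": m,
            "energy": e,
            "time": t,
            "force": e / r,
            "pressure": e / r ** 3,
            "tension": e / r ** 2,        # 2D moduli, surface stress
            "viscosity": m / (r * t),
            "frequency": 1.0 / t,
            "velocity": r / t,
        }
        try:
            return factors[dimension]
        except KeyError:
            raise ValueError(f"unknown dimension {dimension!r}") from None

    @classmethod
    def from_length(cls, r_c: float, T0: float = 300.0,
                    rho_number: float = RHO_NUMBER_DEFAULT) -> "UnitSystem":
        return cls(r_c=r_c, mass=mass_scale(r_c, rho_number), energy=KB * T0, T0=T0)


@dataclass(frozen=True)
class ScalePlan:
    """Down-scaling factor for elastic moduli and viscosity.

    kappa_floor is the smallest admissible scaled bending constant in units of
    k_B T0; below it thermal solvent fluctuations visibly corrugate the shell.
    """

    f_scale: float
    kappa_floor: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.f_scale <= 1.0):
            raise ValueError("f_scale must lie in (0, 1]")
        if self.kappa_floor <= 0:
            raise ValueError("kappa_floor must be positive")


def foppl_von_karman(E2d: float, R0: float, kappa: float) -> float:
    """FvK = E_2d R0^2 / kappa (dimensionless shell shape number)."""
    if E2d <= 0 or R0 <= 0 or kappa <= 0:
        raise ValueError("E2d, R0 and kappa must be positive")
    return E2d * R0 * R0 / kappa


def capillary_number(eta: float, gamma_dot: float, R_eff: float, mu: float) -> float:
    """Ca = eta * gamma_dot * R_eff / mu (viscous vs elastic membrane stress)."""
    if mu <= 0:
        raise ValueError("shear modulus mu must be positive")
    return eta * gamma_dot * R_eff / mu


def downscale_parameters(material, eta_w: float, plan: ScalePlan,
                         strict: bool = True):
    """Multiply all in-plane moduli, kappa and the viscosity by f_scale.

    Returns ``(scaled_material, scaled_viscosity)``.  Measured forces and
    pressures from a run with the scaled material must be divided by
    ``plan.f_scale`` before conversion to physical units.  Raises (or warns if
    ``strict=False``) when the scaled kappa falls below the floor.
    """
    f = plan.f_scale
    scaled = replace(
        material,
        Ka=material.Ka * f,
        mu=material.mu * f,
        muL=material.muL * f,
        c=material.c * f,
        kappa=material.kappa * f,
    )
    if scaled.kappa <= plan.kappa_floor:
        msg = (f"scaled kappa = {scaled.kappa:.3g} k_B T0 is at or below the "
               f"floor {plan.kappa_floor}; thermal wrinkling will contaminate shapes")
        if strict:
            raise ValueError(msg)
        import warnings
        warnings.warn(msg)
    return scaled, eta_w * f


# ---------------------------------------------------------------------------
# Named unit-set presets.  The exact per-set scales live in supplementary data
# not reproduced here; these defaults are reconstructed from main-text
# statements (time step 1e-4 tau ~ 6.5 ps for the GV set; contact-patch
# geometry for the EMB set) and are documented in docs/methods.md.
# ---------------------------------------------------------------------------

def unit_preset(name: str) -> tuple[UnitSystem, ScalePlan]:
    """Return (UnitSystem, ScalePlan) for the 'emb' or 'gv' unit set."""
    if name == "gv":
        # tau(35 nm) = 65 ns, so dt = 1e-4 tau = 6.5 ps; GV diameter 140 nm = 4 r_c
        return UnitSystem.from_length(35e-9), ScalePlan(f_scale=0.079)
    if name == "emb":
        # R0 ~ 1 um (0.65 um contact patch over 2.5% of the surface), r_c = R0/2
        return UnitSystem.from_length(0.5e-6), ScalePlan(f_scale=1e-4)
    raise ValueError(f"unknown unit preset {name!r}; expected 'emb' or 'gv'")
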