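"""Fluid and insect constants, derived lengths, and the capillary-dominance audit.

A water strider resting on or jumping off water interacts with the surface
through thin superhydrophobic legs.  Everything in this module is quasi-static
bookkeeping: the capillary length of the liquid, the quasi-static sinking
depth of a thin rigid cylinder, the elastocapillary flexibility factor of a
bending leg, the dimensionless groups (Omega, M, L, Ba) that parameterize the
jump model, and an order-of-magnitude audit showing that the capillary force
dominates pressure, buoyancy, added-mass, viscous and weight contributions
during a stroke.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FluidProperties",
    "InsectMorphology",
    "LegMechanics",
    "DimensionlessGroups",
    "AuditInputs",
    "WATER",
    "capillary_length",
    "sinking_depth",
    "bending_rigidity",
    "elastocapillary_length",
    "flexibility_factor",
    "leg_mechanics",
    "dimensionless_groups",
    "force_scale_audit",
]

#: Default Young's modulus of insect cuticle (Pa).  Not measured for strider
#: legs in the source data; 10 GPa is a typical sclerotized-cuticle value and
#: is config-overridable.  Headline results use the rigid-leg limit C = 1.
DEFAULT_CUTICLE_MODULUS = 1.0e10

#: Coefficients of the flexibility-factor fit C = (1 + a*L_f**b)**-1,
#: valid for scaled leg lengths L_f < 2.
_FLEX_A = 0.082
_FLEX_B = 3.3
_FLEX_RANGE = 2.0


class DomainError(ValueError):
    """A physical quantity is outside its admissible domain."""


class ConfigurationError(ValueError):
    """A morphology/behaviour combination is internally inconsistent."""


@dataclass(frozen=True)
class FluidProperties:
    """Liquid constants (SI units).

    Attributes
    ----------
    density : float
        Liquid density rho (kg m^-3).
    surface_tension : float
        Surface tension coefficient sigma (N m^-1).
    viscosity : float
        Dynamic viscosity mu (Pa s).
    gravity : float
        Gravitational acceleration g (m s^-2).
    """

    density: float = 998.0
    surface_tension: float = 0.072
    viscosity: float = 1.0e-3
    gravity: float = 9.8

    def __post_init__(self) -> None:
        for name in ("density", "surface_tension", "viscosity", "gravity"):
            if not getattr(self, name) > 0:
                raise DomainError(f"FluidProperties.{name} must be strictly positive")

    @property
    def capillary_length(self) -> float:
        """l_c = sqrt(sigma / (rho g)) (m); ~2.71 mm for water."""
        return math.sqrt(self.surface_tension / (self.density * self.gravity))

    @property
    def velocity_scale(self) -> float:
        """sqrt(g l_c) (m s^-1), the scale of dimensionless body velocity V."""
        return math.sqrt(self.gravity * self.capillary_length)


#: Standard water at the conditions used throughout.
WATER = FluidProperties()


@dataclass(frozen=True)
class InsectMorphology:
    """Morphological traits of a jumping strider (SI units).

    ``support_length`` is the tibia+tarsus length (four-leg average), the part
    of the leg wetted during the pushing stage.  ``rest_height`` is the body
    centre height above the undisturbed surface at rest, so the maximal
    downward reach of a leg is ``max_reach = leg_length - rest_height``.
    """

    body_mass: float
    leg_length: float
    support_length: float
    leg_radius: float
    rest_height: float
    cuticle_modulus: float = DEFAULT_CUTICLE_MODULUS
    name: str = ""

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise DomainError("body_mass must be strictly positive")
        if not self.leg_radius > 0:
            raise DomainError("leg_radius must be strictly positive")
        if not self.cuticle_modulus > 0:
            raise DomainError("cuticle_modulus must be strictly positive")
        if self.support_length > self.leg_length:
            raise DomainError("support_length must not exceed leg_length")
        if not 0 < self.rest_height < self.leg_length:
            raise ConfigurationError(
                "rest_height must lie in (0, leg_length) so that max_reach > 0"
            )

    @property
    def max_reach(self) -> float:
        """Delta_l = l_l - y_i (m), the maximal downward reach of a leg."""
        return self.leg_length - self.rest_height


def capillary_length(fluid: FluidProperties) -> float:
    """Capillary length l_c = sqrt(sigma/(rho g)) of the liquid (m)."""
    return fluid.capillary_length


def sinking_depth(fluid: FluidProperties) -> float:
    """Quasi-static piercing depth of a long thin rigid cylinder (m).

    A superhydrophobic thin cylinder pressed slowly into the surface breaks
    the meniscus at depth sqrt(2) * l_c (about 3.8 mm for water); beyond it
    the surface cannot statically support the leg and the leg sinks.
    """
    return math.sqrt(2.0) * fluid.capillary_length


def bending_rigidity(morph: InsectMorphology) -> float:
    """Leg bending rigidity B = pi E r^4 / 4 (N m^2)."""
    return math.pi * morph.cuticle_modulus * morph.leg_radius**4 / 4.0


def elastocapillary_length(morph: InsectMorphology, fluid: FluidProperties) -> float:
    """Modified elastocapillary length l_ec = (B l_c / sigma)^(1/4) (m).

    Legs much longer than l_ec bend appreciably under capillary loading.
    """
    B = bending_rigidity(morph)
    return (B * fluid.capillary_length / fluid.surface_tension) ** 0.25


def flexibility_factor(scaled_length: float) -> float:
    """Flexibility factor C = (1 + 0.082 L_f^3.3)^-1 of a bending leg.

    ``scaled_length`` is L_f = l_w / l_ec.  C multiplies the wetted length to
    give the effective wetted length C*l_w of a flexible leg; C = 1 is the
    rigid limit.  The closed-form fit holds for L_f < 2; for larger L_f the
    formula is still evaluated but a warning is emitted.

    Raises
    ------
    DomainError
        If ``scaled_length`` is negative.
    """
    if scaled_length < 0:
        raise DomainError("scaled leg length L_f must be non-negative")
    if scaled_length >= _FLEX_RANGE:
        warnings.warn(
            f"flexibility factor evaluated at L_f={scaled_length:.3g} >= 2, "
            "outside the fitted range of the closed form",
            stacklevel=2,
        )
    return 1.0 / (1.0 + _FLEX_A * scaled_length**_FLEX_B)


@dataclass(frozen=True)
class LegMechanics:
    """Derived elastocapillary quantities of a leg."""

    bending_rigidity: float
    elastocapillary_length: float
    scaled_length: float
    flexibility: float


def leg_mechanics(
    morph: InsectMorphology,
    fluid: FluidProperties,
    wetted_length: float | None = None,
) -> LegMechanics:
    """Bending rigidity, elastocapillary length, L_f and C for one leg.

    ``wetted_length`` defaults to the support (tibia+tarsus) length.
    """
    lw = morph.support_length if wetted_length is None else wetted_length
    B = bending_rigidity(morph)
    lec = elastocapillary_length(morph, fluid)
    Lf = lw / lec
    return LegMechanics(B, lec, Lf, flexibility_factor(Lf))


@dataclass(frozen=True)
class DimensionlessGroups:
    """The dimensionless groups governing a vertical jump.

    Omega = omega * sqrt(l_c/g) is the scaled leg-rotation rate, M is the body
    mass in units of the maximal mass of water the wetted legs can displace,
    L = Delta_l / l_c is the scaled maximal reach, and Ba = m g/(sigma P) is
    the Baudoin number over the wetted perimeter P.  With C = 1 and
    P = 8 l_t, M = 8 Ba identically.
    """

    Omega: float
    mass_index: float
    reach: float
    baudoin: float
    flexibility: float = 1.0


def dimensionless_groups(
    morph: InsectMorphology,
    fluid: FluidProperties,
    omega: float,
    flexibility: float = 1.0,
    n_legs: int = 4,
) -> DimensionlessGroups:
    """Compute (Omega, M, L, Ba) for a morphology, fluid and stroke rate.

    Parameters
    ----------
    omega : float
        Angular velocity of leg rotation (rad s^-1), assumed constant over
        the jump.
    flexibility : float
        Flexibility factor C in (0, 1]; 1 is the rigid-leg limit used for
        headline results.  Pass ``leg_mechanics(...).flexibility`` to account
        for leg bending.
    n_legs : int
        Number of propelling legs; the wetted perimeter is P = 2 n_legs l_t
        (two contact lines per thin cylinder).
    """
    if not omega > 0:
        raise DomainError("omega must be strictly positive")
    if not 0 < flexibility <= 1:
        raise DomainError("flexibility factor C must lie in (0, 1]")
    if morph.max_reach <= 0:
        raise ConfigurationError("morphology has non-positive max reach")
    lc = fluid.capillary_length
    Omega = omega * math.sqrt(lc / fluid.gravity)
    M = morph.body_mass / (fluid.density * lc**2 * flexibility * morph.support_length)
    L = morph.max_reach / lc
    P = 2.0 * n_legs * morph.support_length
    Ba = morph.body_mass * fluid.gravity / (fluid.surface_tension * P)
    return DimensionlessGroups(Omega, M, L, Ba, flexibility)


@dataclass(frozen=True)
class AuditInputs:
    """Reference scales for the order-of-magnitude force audit.

    Defaults are the measured exemplar for a medium-sized strider
    (*Gerris gracilicornis*): wetted length 7.5 mm, dimple growth rate
    0.15 m s^-1, dimple depth 3 mm, takeoff speed ~1 m s^-1, and a per-leg
    detachment energy loss of 1e-9 J.
    """

    wetted_length: float = 7.5e-3
    descent_speed: float = 0.15
    dimple_depth: float = 3.0e-3
    takeoff_speed: float = 1.0
    detachment_energy: float = 1.0e-9
    n_legs: int = 4

    def __post_init__(self) -> None:
        for name in ("wetted_length", "dimple_depth", "takeoff_speed"):
            if not getattr(self, name) > 0:
                raise DomainError(f"AuditInputs.{name} must be strictly positive")
        if self.descent_speed < 0 or self.detachment_energy < 0:
            raise DomainError("descent_speed and detachment_energy must be >= 0")


def _order(value: float) -> float:
    """floor(log10(value)); NaN for non-positive values (static limits)."""
    if value <= 0:
        return math.nan
    return math.floor(math.log10(value))


def force_scale_audit(
    inputs: AuditInputs,
    fluid: FluidProperties,
    morph: InsectMorphology,
) -> pd.DataFrame:
    """Order-of-magnitude audit of all forces against the capillary force.

    Computes the six force scales F_s = sigma l_w (capillary),
    F_p = rho U^2 r l_w (pressure), F_b = rho g r h l_w (buoyancy),
    F_a = rho r^2 l_w U^2 / h (added mass), F_v = mu r l_w U / l_c (viscous)
    and F_w = m g (weight), plus the detachment-energy to kinetic-energy
    ratio E_d/E_k with E_k = m v^2 and E_d summed over ``n_legs`` legs.

    Returns a table with columns ``ratio_name, numerator, denominator, value,
    order`` where ``order = floor(log10(value))``.  With the printed exemplar
    inputs the orders are -2, -2, -4, -5, -1 (forces) and -4 (energy),
    establishing that surface tension dominates the stroke.
    """
    lw, U, h = inputs.wetted_length, inputs.descent_speed, inputs.dimple_depth
    r = morph.leg_radius
    rho, g, mu = fluid.density, fluid.gravity, fluid.viscosity
    lc = fluid.capillary_length
    if h == 0 and U != 0:
        raise DomainError("degenerate dimple: h = 0 with non-zero descent speed")

    F_s = fluid.surface_tension * lw
    F_p = rho * U**2 * r * lw
    F_b = rho * g * r * h * lw
    F_a = rho * r**2 * lw * U**2 / h
    F_v = mu * r * lw * U / lc
    F_w = morph.body_mass * g
    E_k = morph.body_mass * inputs.takeoff_speed**2
    E_d = inputs.n_legs * inputs.detachment_energy

    rows = [
        ("F_p/F_s", F_p, F_s),
        ("F_b/F_s", F_b, F_s),
        ("F_a/F_s", F_a, F_s),
        ("F_v/F_s", F_v, F_s),
        ("F_w/F_s", F_w, F_s),
        ("E_d/E_k", E_d, E_k),
    ]
    records = []
    for name, num, den in rows:
        value = num / den
        records.append(
            {
                "ratio_name": name,
                "numerator": num,
                "denominator": den,
                "value": value,
                "order": _order(value),
            }
        )
    return pd.DataFrame.from_records(records)
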