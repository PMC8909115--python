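"""Eulerian gas-phase description of fully developed pipe flow.

The Lagrangian tracker only needs the mean axial velocity profile and
isotropic fluctuation statistics, so instead of solving the RANS k-epsilon
equations this module uses the closed-form fully-developed closures:

* laminar: the Hagen-Poiseuille parabola ``u(r) = 2*u_mean*(1 - (r/R)**2)``;
* turbulent: a wall-resolved analytic profile (Reichardt's law of the wall
  by default, which covers the viscous sublayer, buffer layer and log
  region; the 1/7th-power-law profile as an option), rescaled so the area
  average equals the bulk velocity, plus the standard pipe correlations for
  turbulence intensity ``I = 0.16*Re**(-1/8)`` and mixing length
  ``l = 0.07*D`` (with ``C_mu = 0.09``) to obtain the turbulence kinetic
  energy ``k``, its dissipation rate ``eps`` and the timescales the
  dispersion model needs.

The near-wall behaviour of the mean profile matters here: particle-wall
collision counts are controlled by how long particles linger in the
slow-moving wall layer, which a power law (no viscous sublayer) badly
misrepresents.  The friction velocity comes from the Blasius correlation
``f = 0.316 Re**(-1/4)``, ``u_tau = u_mean * sqrt(f/8)``.

All quantities are SI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import FullyDevelopedFlowWarning, InvalidParameterError, RegimeWarning

__all__ = [
    "PipeGeometry",
    "GasProperties",
    "FlowProfile",
    "reynolds_number",
    "turbulence_quantities",
    "build_profile",
    "AIR",
    "VACUUM_PERMITTIVITY",
    "LAMINAR_TURBULENT_RE",
    "C_MU",
    "EDDY_LIFETIME_CONSTANT",
]

#: Absolute permittivity of the gas, F/m (vacuum value; air differs by <0.1%).
VACUUM_PERMITTIVITY = 8.854e-12

#: Transition Reynolds number used for automatic regime detection.
LAMINAR_TURBULENT_RE = 2300.0

#: Standard k-epsilon model constant.
C_MU = 0.09

#: Eddy-lifetime constant of the discrete-random-walk dispersion model,
#: tau_e = EDDY_LIFETIME_CONSTANT * k / eps.
EDDY_LIFETIME_CONSTANT = 0.30

#: von Karman constant (Reichardt profile).
VON_KARMAN = 0.41


def reichardt_uplus(yplus):
    """Reichardt's composite law of the wall, ``u+`` as a function of ``y+``.

    Smoothly spans the viscous sublayer (u+ ~ y+), buffer layer and the
    logarithmic region; monotone in y+, zero at the wall.
    """
    yp = np.asarray(yplus, dtype=float)
    u = (1.0 / VON_KARMAN) * np.log1p(VON_KARMAN * yp) + 7.8 * (
        1.0 - np.exp(-yp / 11.0) - (yp / 11.0) * np.exp(-yp / 3.0)
    )
    return u if u.ndim else float(u)


@dataclass(frozen=True)
class PipeGeometry:
    """Straight circular pipe, horizontal axis.

    Parameters
    ----------
    length : float
        Axial extent, m.
    inner_diameter : float
        Inner diameter, m.
    """

    length: float
    inner_diameter: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.inner_diameter <= 0:
            raise InvalidParameterError(
                f"pipe length and diameter must be positive, got "
                f"length={self.length}, inner_diameter={self.inner_diameter}"
            )
        if self.length / self.inner_diameter < 10.0:
            warnings.warn(
                f"L/D = {self.length / self.inner_diameter:.1f} < 10: the "
                "fully-developed-profile assumption is questionable",
                FullyDevelopedFlowWarning,
                stacklevel=2,
            )

    @property
    def radius(self) -> float:
        return 0.5 * self.inner_diameter

    @property
    def cross_section_area(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class GasProperties:
    """Carrier-gas constants (defaults: dry air at room temperature)."""

    density: float = 1.2  # kg/m^3
    dynamic_viscosity: float = 1.81e-5  # Pa s
    permittivity_vacuum: float = VACUUM_PERMITTIVITY  # F/m

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidParameterError("gas density and viscosity must be positive")
        if self.permittivity_vacuum != VACUUM_PERMITTIVITY:
            raise InvalidParameterError(
                "permittivity_vacuum is a physical constant fixed to 8.854e-12 F/m"
            )


#: Default carrier gas.
AIR = GasProperties()


def reynolds_number(
    geometry: PipeGeometry, gas: GasProperties, mean_velocity: float
) -> float:
    """Pipe Reynolds number ``rho * u * D / mu``.

    ``mean_velocity`` may be zero (Re = 0); all other inputs must be positive.
    """
    if mean_velocity < 0:
        raise InvalidParameterError(f"mean_velocity must be >= 0, got {mean_velocity}")
    return gas.density * mean_velocity * geometry.inner_diameter / gas.dynamic_viscosity


def turbulence_quantities(
    reynolds: float,
    mean_velocity: float,
    geometry: PipeGeometry,
) -> tuple[float, float, float]:
    """Turbulence kinetic energy, dissipation and integral timescale.

    Uses the standard fully-developed-pipe correlations:

    * intensity ``I = 0.16 * Re**(-1/8)``;
    * ``k = 1.5 * (u_mean * I)**2``;
    * ``eps = C_mu**(3/4) * k**(3/2) / l`` with ``l = 0.07 * D``;
    * integral timescale ``tau_L = k / eps``.

    Returns
    -------
    (k, eps, tau_L) : tuple of float
        m^2/s^2, m^2/s^3, s — all strictly positive.
    """
    if reynolds <= 0:
        raise InvalidParameterError(f"Reynolds number must be positive, got {reynolds}")
    if mean_velocity <= 0:
        raise InvalidParameterError("mean_velocity must be positive")
    intensity = 0.16 * reynolds ** (-1.0 / 8.0)
    k = 1.5 * (mean_velocity * intensity) ** 2
    length_scale = 0.07 * geometry.inner_diameter
    eps = C_MU**0.75 * k**1.5 / length_scale
    tau_l = k / eps
    return k, eps, tau_l


@dataclass(frozen=True)
class FlowProfile:
    """Mean axial velocity field plus turbulence statistics for one condition.

    ``integral_timescale`` is the characteristic fluid timescale ``k/eps``
    used for Stokes-number classification; ``eddy_lifetime`` is the (shorter)
    interaction time of the discrete-random-walk dispersion model.  Both are
    ``inf`` in the laminar regime, where there are no eddies.
    """

    mean_velocity: float
    regime: str  # "laminar" | "turbulent"
    reynolds: float
    geometry: PipeGeometry
    turb_kinetic_energy: float = 0.0
    turb_dissipation: float = 0.0
    integral_timescale: float = math.inf
    eddy_lifetime: float = math.inf
    eddy_length: float = field(default=math.inf)
    profile_model: str = "law_of_the_wall"  # or "power_law"
    friction_velocity: float = 0.0  # u_tau, m/s (turbulent only)
    kinematic_viscosity: float = 1.81e-5 / 1.2  # m^2/s
    velocity_scale: float = 0.0  # m/s per u+ unit (law-of-the-wall profile)

    @property
    def fluctuation_rms(self) -> float:
        """Per-component rms of the isotropic velocity fluctuation, sqrt(2k/3)."""
        return math.sqrt(2.0 * self.turb_kinetic_energy / 3.0)

    @property
    def centerline_velocity(self) -> float:
        if self.regime == "laminar":
            return 2.0 * self.mean_velocity
        if self.profile_model == "power_law":
            return (60.0 / 49.0) * self.mean_velocity
        yplus_max = self.geometry.radius * self.friction_velocity / self.kinematic_viscosity
        return self.velocity_scale * reichardt_uplus(yplus_max)

    def wall_units(self, distance_from_wall):
        """Convert a wall distance (m) to viscous wall units y+."""
        if self.regime == "laminar":
            return np.zeros_like(np.asarray(distance_from_wall, dtype=float))
        return (
            np.asarray(distance_from_wall, dtype=float)
            * self.friction_velocity
            / self.kinematic_viscosity
        )

    def axial_velocity_at(self, r):
        """Mean axial velocity at radial coordinate ``r`` (scalar or array), m/s.

        Satisfies no-slip at the wall and area-averages to ``mean_velocity``.
        """
        r = np.asarray(r, dtype=float)
        radius = self.geometry.radius
        if np.any(r < 0) or np.any(r > radius * (1 + 1e-12)):
            raise InvalidParameterError("radial coordinate outside [0, R]")
        s = np.clip(r / radius, 0.0, 1.0)
        if self.regime == "laminar":
            u = 2.0 * self.mean_velocity * (1.0 - s**2)
        elif self.profile_model == "power_law":
            u = self.centerline_velocity * (1.0 - s) ** (1.0 / 7.0)
        else:
            yplus = self.wall_units(radius * (1.0 - s))
            u = self.velocity_scale * reichardt_uplus(yplus)
        return u if u.ndim else float(u)


def build_profile(
    geometry: PipeGeometry,
    gas: GasProperties,
    mean_velocity: float,
    regime: str = "auto",
    eddy_lifetime_constant: float = EDDY_LIFETIME_CONSTANT,
    profile_model: str = "law_of_the_wall",
) -> FlowProfile:
    """Construct the flow description for one pipe/gas/velocity condition.

    Parameters
    ----------
    regime : {"auto", "laminar", "turbulent"}
        "auto" applies the Re = 2300 threshold.  An explicit "turbulent"
        below the threshold is honoured with a warning (transitional pipe
        flows are routinely modelled as turbulent).
    profile_model : {"law_of_the_wall", "power_law"}
        Turbulent mean-profile closure.  The Reichardt law of the wall
        resolves the viscous sublayer (it controls near-wall particle
        residence); the 1/7th power law is the cruder classic alternative.
    """
    if mean_velocity <= 0:
        raise InvalidParameterError("mean_velocity must be positive")
    if regime not in ("auto", "laminar", "turbulent"):
        raise InvalidParameterError(f"unknown regime {regime!r}")
    if profile_model not in ("law_of_the_wall", "power_law"):
        raise InvalidParameterError(f"unknown profile model {profile_model!r}")
    re = reynolds_number(geometry, gas, mean_velocity)
    if regime == "auto":
        regime = "turbulent" if re >= LAMINAR_TURBULENT_RE else "laminar"
    elif regime == "turbulent" and re < LAMINAR_TURBULENT_RE:
        warnings.warn(
            f"regime forced to turbulent at Re = {re:.0f} < {LAMINAR_TURBULENT_RE:.0f}",
            RegimeWarning,
            stacklevel=2,
        )
    nu = gas.dynamic_viscosity / gas.density
    if regime == "laminar":
        return FlowProfile(
            mean_velocity=mean_velocity,
            regime="laminar",
            reynolds=re,
            geometry=geometry,
            kinematic_viscosity=nu,
        )
    k, eps, tau_l = turbulence_quantities(re, mean_velocity, geometry)
    # Blasius friction factor -> friction velocity
    f_blasius = 0.316 * re ** (-0.25)
    u_tau = mean_velocity * math.sqrt(f_blasius / 8.0)
    velocity_scale = 0.0
    if profile_model == "law_of_the_wall":
        # rescale Reichardt's u+ so the area average is exactly u_mean
        s = np.linspace(0.0, 1.0, 4001)  # r/R
        yplus = geometry.radius * (1.0 - s) * u_tau / nu
        uplus = reichardt_uplus(yplus)
        mean_uplus = 2.0 * np.trapezoid(uplus * s, s)
        velocity_scale = mean_velocity / mean_uplus
    return FlowProfile(
        mean_velocity=mean_velocity,
        regime="turbulent",
        reynolds=re,
        geometry=geometry,
        turb_kinetic_energy=k,
        turb_dissipation=eps,
        integral_timescale=tau_l,
        eddy_lifetime=eddy_lifetime_constant * k / eps,
        # with eps = C_mu^(3/4) k^(3/2) / l this is exactly l = 0.07 D
        eddy_length=C_MU**0.75 * k**1.5 / eps,
        profile_model=profile_model,
        friction_velocity=u_tau,
        kinematic_viscosity=nu,
        velocity_scale=velocity_scale,
    )
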