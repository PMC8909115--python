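"""Condenser-model tribocharging algebra.

The particle-wall contact is treated as a parallel-plate capacitor: on each
impact, charge flows across a critical gap ``z0`` driven by the contact
potential difference ``V_c`` between the two materials (the difference of
their work functions, divided by the elementary charge).  For a particle
undergoing ``n`` wall collisions along a pipe segment, the acquired charge
per unit mass is

    dq/m = 6 eps0 V_c n k S / (pi D_p^3 rho_p z0),

with ``k`` a dimensionless charging efficiency and ``S`` the maximum
Hertzian contact area of an elastic impact,

    S = 1.36 k_e^(2/5) rho_p^(2/5) D_p^2 v_i^(4/5),
    k_e = (1 - nu_1^2)/E_1 + (1 - nu_2^2)/E_2.

The saturating form (charge exchange self-limits as the particle's own
charge builds an opposing field) is

    dq/m = (qm_inf - qm_0) * exp(-n_before/n0) * (1 - exp(-n_segment/n0)),

whose small-n linearization is the linear law above.

Important caveat: ``k`` and ``z0`` are not measurable independently here, so
any absolute ``V_c`` is defined only up to the factor ``k / z0``.  Every
correlation between ``V_c`` and composition is invariant to this scale; the
default ``k = 1`` and ``z0 = 2.5e-7 m`` fix the scale for reporting only.

Charge-per-mass unit conversion used throughout: 1 C/kg = 1e6 nC/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._errors import InvalidParameterError, UncharacterizableError
from .flow_field import VACUUM_PERMITTIVITY

__all__ = [
    "ContactPair",
    "ChargeRelaxation",
    "ChargeResult",
    "elasticity_parameter",
    "contact_area",
    "charge_saturation",
    "charge_to_mass",
    "invert_cpd",
    "NC_PER_G_PER_C_PER_KG",
]

#: 1 C/kg expressed in nC/g.
NC_PER_G_PER_C_PER_KG = 1e6


@dataclass(frozen=True)
class ContactPair:
    """Electro-mechanical parameters of a particle-wall material pairing.

    Wall defaults are PTFE (the tribocharging tube material); the contact
    potential difference may be ``None`` when the pair is used for
    inversion (measured charge -> V_c).
    """

    contact_potential_difference: float | None = None  # V
    charging_efficiency: float = 1.0  # dimensionless k
    critical_gap: float = 2.5e-7  # m, z0
    wall_youngs_modulus: float = 0.5e9  # Pa, PTFE
    wall_poisson_ratio: float = 0.46  # PTFE

    def __post_init__(self) -> None:
        if self.charging_efficiency <= 0:
            raise InvalidParameterError("charging_efficiency must be positive")
        if self.critical_gap <= 0:
            raise InvalidParameterError("critical_gap must be positive")
        if self.wall_youngs_modulus <= 0:
            raise InvalidParameterError("wall Young's modulus must be positive")
        if not 0.0 <= self.wall_poisson_ratio < 0.5:
            raise InvalidParameterError("wall Poisson ratio must lie in [0, 0.5)")


@dataclass(frozen=True)
class ChargeRelaxation:
    """Parameters of the exponential charge-saturation law."""

    qm0: float  # C/kg at x = 0
    qm_inf: float  # C/kg at x -> inf
    n0: float  # characteristic collision number

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise InvalidParameterError("n0 must be positive")
        if not math.isfinite(self.qm_inf):
            raise InvalidParameterError("qm_inf must be finite")


@dataclass(frozen=True)
class ChargeResult:
    """Forward-model output for one condition."""

    delta_qm: float  # C/kg
    contact_area: float  # m^2
    elasticity_parameter: float  # 1/Pa

    @property
    def delta_qm_nc_per_g(self) -> float:
        return self.delta_qm * NC_PER_G_PER_C_PER_KG


def elasticity_parameter(e1: float, v1: float, e2: float, v2: float) -> float:
    """Combined compliance ``k_e = (1-v1^2)/E1 + (1-v2^2)/E2`` of two bodies, 1/Pa.

    Symmetric under swapping the bodies; the rigid-wall limit E2 -> inf
    leaves only the particle term.
    """
    for e, v in ((e1, v1), (e2, v2)):
        if e <= 0:
            raise InvalidParameterError("Young's moduli must be positive")
        if not 0.0 <= v < 0.5:
            raise InvalidParameterError("Poisson ratios must lie in [0, 0.5)")
    return (1.0 - v1**2) / e1 + (1.0 - v2**2) / e2


def contact_area(ke: float, rho_p: float, dp: float, vi: float) -> float:
    """Maximum Hertzian contact area of an elastic sphere-wall impact, m^2.

    ``S = 1.36 k_e^(2/5) rho_p^(2/5) D_p^2 v_i^(4/5)``; zero exactly when
    the impact speed is zero.
    """
    if ke < 0 or rho_p < 0 or dp < 0 or vi < 0:
        raise InvalidParameterError("contact_area inputs must be non-negative")
    return 1.36 * ke**0.4 * rho_p**0.4 * dp**2 * vi**0.8


def charge_saturation(
    relax: ChargeRelaxation, n_before: float, n_segment: float
) -> float:
    """Charge-per-mass gained over a segment with ``n_segment`` collisions.

    ``dq/m = (qm_inf - qm0) exp(-n_before/n0) (1 - exp(-n_segment/n0))``:
    the gain of a fresh segment is damped by the saturation already reached
    over the ``n_before`` earlier collisions.  Consecutive segments
    telescope: (n1 then n2) sums to the single-segment value for n1 + n2.
    """
    if n_before < 0 or n_segment < 0:
        raise InvalidParameterError("collision numbers must be non-negative")
    return (
        (relax.qm_inf - relax.qm0)
        * math.exp(-n_before / relax.n0)
        * (1.0 - math.exp(-n_segment / relax.n0))
    )


def charge_to_mass(
    pair: ContactPair, s: float, n: float, dp: float, rho_p: float
) -> float:
    """Forward condenser model: charge per mass after ``n`` collisions, C/kg.

    ``dq/m = 6 eps0 V_c n k S / (pi D_p^3 rho_p z0)`` — valid when the
    initial particle charge is negligible (small-n, far from saturation).
    """
    if pair.contact_potential_difference is None:
        raise InvalidParameterError("ContactPair has no contact_potential_difference")
    if dp <= 0 or rho_p <= 0:
        raise InvalidParameterError("particle diameter and density must be positive")
    if s < 0 or n < 0:
        raise InvalidParameterError("contact area and collision number must be >= 0")
    return (
        6.0
        * VACUUM_PERMITTIVITY
        * pair.contact_potential_difference
        * n
        * pair.charging_efficiency
        * s
        / (math.pi * dp**3 * rho_p * pair.critical_gap)
    )


def invert_cpd(
    measured_qm: float,
    s: float,
    n: float,
    dp: float,
    rho_p: float,
    pair_mech: ContactPair,
) -> float:
    """Invert the condenser model: measured charge per mass (C/kg) -> V_c, V.

    Exact algebraic inverse of :func:`charge_to_mass`; raises
    :class:`UncharacterizableError` when the particle never collided or the
    contact area vanishes (no charge transfer channel exists).
    """
    if dp <= 0 or rho_p <= 0:
        raise InvalidParameterError("particle diameter and density must be positive")
    if n <= 0 or s <= 0:
        raise UncharacterizableError(
            f"uncharacterizable: no collisions/contact (n = {n}, S = {s})"
        )
    return (
        measured_qm
        * math.pi
        * dp**3
        * rho_p
        * pair_mech.critical_gap
        / (6.0 * VACUUM_PERMITTIVITY * n * pair_mech.charging_efficiency * s)
    )
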