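"""End-to-end powder characterization pipeline.

For each sieved powder fraction (known volume mean diameter D4,3, measured
charge-to-mass ratio, protein content), this module predicts the particle-
wall mean collision number and impact speed at the rig conditions, computes
the Hertzian contact area, inverts the condenser model for the contact
potential difference V_c, and correlates V_c with composition.  V_c depends
on the work functions of the contacting surfaces, which in turn track the
chemical composition (e.g. protein content) of the powder — so the
correlation is the quantity of interest, and it is invariant to the unknown
charging-efficiency/critical-gap scale factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InvalidParameterError, DiluteLoadingWarning, UncharacterizableError
from .flow_field import AIR, GasProperties
from .io_fixtures import derive_seed, load_fixture
from .particle_tracking import Condition, TrackingConfig, run_condition
from .tribocharge import (
    ContactPair,
    NC_PER_G_PER_C_PER_KG,
    contact_area,
    elasticity_parameter,
    invert_cpd,
)

__all__ = [
    "SievedFraction",
    "RigConfig",
    "Correlation",
    "CharacterizationResult",
    "airflow_to_velocity",
    "fractions_from_frame",
    "load_table2_fractions",
    "characterize",
    "correlate",
]

#: One-way-coupling threshold on the solids volume fraction.
DILUTE_VOLUME_FRACTION = 1e-6


@dataclass(frozen=True)
class SievedFraction:
    """One sieved powder fraction with its measured properties."""

    mesh_label: str
    d43_um: float
    protein_wt_pct: float
    qm_nc_per_g: float
    d43_sd: float = 0.0
    protein_sd: float = 0.0
    qm_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.d43_um <= 0 or self.protein_wt_pct <= 0 or self.qm_nc_per_g <= 0:
            raise InvalidParameterError(
                "fraction central values (D4,3, protein, charge) must be positive"
            )
        if min(self.d43_sd, self.protein_sd, self.qm_sd) < 0:
            raise InvalidParameterError("spreads must be non-negative")


@dataclass(frozen=True)
class RigConfig:
    """Tribocharging rig: PTFE tube fed by a fluidized sample feeder.

    Defaults describe the bench rig: 1.5 m x 4.76 mm PTFE tube, 7 L/min of
    dry air, 1 g/min of powder.  ``air_velocity_override`` replaces the
    velocity derived from the airflow rate (e.g. to reuse collision numbers
    simulated at a different nominal velocity).  The transitional Reynolds
    number (~2100 at rig conditions) is treated as turbulent by default.
    """

    tube_length: float = 1.5  # m
    tube_inner_diameter: float = 4.76e-3  # m
    airflow_rate_lpm: float = 7.0  # L/min
    solid_mass_rate_g_min: float = 1.0  # g/min
    particle_density: float = 1440.0  # kg/m^3 (flour)
    air_velocity_override: float | None = None  # m/s
    regime: str = "turbulent"

    def __post_init__(self) -> None:
        if min(
            self.tube_length,
            self.tube_inner_diameter,
            self.airflow_rate_lpm,
            self.solid_mass_rate_g_min,
            self.particle_density,
        ) <= 0:
            raise InvalidParameterError("rig parameters must be positive")
        phi = self.solids_volume_fraction
        if phi >= DILUTE_VOLUME_FRACTION:
            warnings.warn(
                f"solids volume fraction {phi:.2e} >= {DILUTE_VOLUME_FRACTION:g}: "
                "strict one-way coupling is not guaranteed",
                DiluteLoadingWarning,
                stacklevel=2,
            )

    @property
    def air_velocity(self) -> float:
        if self.air_velocity_override is not None:
            return self.air_velocity_override
        return airflow_to_velocity(self.airflow_rate_lpm, self.tube_inner_diameter)

    @property
    def solids_volume_fraction(self) -> float:
        """Volumetric solids flow over volumetric gas flow."""
        q_gas = self.airflow_rate_lpm / 60_000.0  # m^3/s
        q_solid = self.solid_mass_rate_g_min / 60_000.0 / self.particle_density
        return q_solid / q_gas


def airflow_to_velocity(flow_rate_lpm: float, inner_diameter: float) -> float:
    """Convert a volumetric airflow rate (L/min) to mean pipe velocity (m/s)."""
    if flow_rate_lpm < 0 or inner_diameter <= 0:
        raise InvalidParameterError("flow rate must be >= 0 and diameter positive")
    q = flow_rate_lpm / 60_000.0
    area = math.pi * inner_diameter**2 / 4.0
    return q / area


class Correlation(NamedTuple):
    pearson_r: float
    spearman_rho: float
    slope: float
    intercept: float


def correlate(x: Sequence[float], y: Sequence[float]) -> Correlation:
    """Pearson and Spearman correlations plus the OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidParameterError("correlate needs equal-length vectors of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("correlate requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError("undefined correlation: zero variance input")
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    fit = stats.linregress(x, y)
    return Correlation(float(pearson), float(spearman), float(fit.slope), float(fit.intercept))


@dataclass
class CharacterizationResult:
    """Per-fraction predictions plus summary correlations."""

    table: pd.DataFrame
    vc_vs_protein: Correlation | None
    qm_vs_collisions: Correlation | None
    uncharacterizable: list[str] = field(default_factory=list)


def fractions_from_frame(frame: pd.DataFrame) -> list[SievedFraction]:
    """Build :class:`SievedFraction` objects from a fixture-style DataFrame."""
    return [
        SievedFraction(
            mesh_label=str(r["mesh_label"]),
            d43_um=float(r["d43_um"]),
            protein_wt_pct=float(r["protein_wt_pct"]),
            qm_nc_per_g=float(r["qm_nc_per_g"]),
            d43_sd=float(r.get("d43_sd", 0.0)),
            protein_sd=float(r.get("protein_sd", 0.0)),
            qm_sd=float(r.get("qm_sd", 0.0)),
        )
        for _, r in frame.iterrows()
    ]


def load_table2_fractions() -> list[SievedFraction]:
    """The packaged sieved-fraction measurements as fraction objects."""
    return fractions_from_frame(load_fixture("table2"))


def _fraction_seed(master_seed: int, frac: SievedFraction, rig: RigConfig) -> int:
    # depends only on the physical condition, so permuting the input list
    # leaves every per-fraction output unchanged
    return derive_seed(
        master_seed, "fraction", f"{frac.d43_um:.6g}", f"{rig.particle_density:.6g}"
    )


def characterize(
    fractions: Sequence[SievedFraction],
    rig: RigConfig | None = None,
    collision_model: str = "simulator",
    pair: ContactPair | None = None,
    particle_youngs_modulus: float = 2.0e9,
    particle_poisson_ratio: float = 0.3,
    gas: GasProperties = AIR,
    seed: int = 0,
    surrogate=None,
    tracking: TrackingConfig | None = None,
) -> CharacterizationResult:
    """Estimate the contact potential difference of each fraction.

    Each fraction is represented by its D4,3 as a single monodisperse size.
    ``collision_model="simulator"`` runs the Lagrangian tracker per fraction;
    ``"surrogate"`` takes the collision number from a trained
    :class:`~tribochar.surrogate_ann.SurrogateEnsemble` (the mean impact
    speed still comes from a tracker run, since the surrogate predicts only
    collision numbers).  Fractions with no predicted collisions are excluded
    from the correlations and listed as uncharacterizable.
    """
    if not fractions:
        raise InvalidParameterError("fractions must be non-empty")
    if collision_model not in ("simulator", "surrogate"):
        raise InvalidParameterError(f"unknown collision model {collision_model!r}")
    if collision_model == "surrogate" and surrogate is None:
        raise InvalidParameterError("surrogate model requested but none supplied")
    rig = rig or RigConfig()
    pair = pair or ContactPair()
    tracking = tracking or TrackingConfig()

    ke = elasticity_parameter(
        particle_youngs_modulus,
        particle_poisson_ratio,
        pair.wall_youngs_modulus,
        pair.wall_poisson_ratio,
    )
    velocity = rig.air_velocity

    rows = []
    uncharacterizable: list[str] = []
    for frac in fractions:
        cond = Condition(
            particle_diameter=frac.d43_um * 1e-6,
            particle_density=rig.particle_density,
            pipe_length=rig.tube_length,
            pipe_diameter=rig.tube_inner_diameter,
            air_velocity=velocity,
            regime=rig.regime,
        )
        cfg = replace(tracking, rng_seed=_fraction_seed(seed, frac, rig))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = run_condition(cond, gas=gas, config=cfg)
        v_i = summary.mean_normal_impact_speed
        if collision_model == "simulator":
            n = summary.mean_collision_number
        else:
            feature = np.array(
                [[
                    frac.d43_um,
                    rig.particle_density,
                    rig.tube_inner_diameter,
                    rig.tube_length,
                    velocity,
                    cfg.initial_vertical_speed,
                ]]
            )
            n = float(surrogate.predict(feature)[0])

        s = contact_area(ke, rig.particle_density, frac.d43_um * 1e-6, v_i)
        row = {
            "mesh_label": frac.mesh_label,
            "d43_um": frac.d43_um,
            "protein_wt_pct": frac.protein_wt_pct,
            "qm_nc_per_g": frac.qm_nc_per_g,
            "mean_collision_number": n,
            "mean_normal_impact_speed": v_i,
            "contact_area_m2": s,
        }
        try:
            vc = invert_cpd(
                frac.qm_nc_per_g / NC_PER_G_PER_C_PER_KG,
                s,
                n,
                frac.d43_um * 1e-6,
                rig.particle_density,
                pair,
            )
        except UncharacterizableError:
            row["contact_potential_difference_v"] = np.nan
            uncharacterizable.append(frac.mesh_label)
        else:
            row["contact_potential_difference_v"] = vc
        rows.append(row)

    table = pd.DataFrame(rows)
    usable = table["contact_potential_difference_v"].notna()
    vc_corr = qm_corr = None
    if usable.sum() >= 3:
        sub = table[usable]
        try:
            vc_corr = correlate(
                sub["protein_wt_pct"], sub["contact_potential_difference_v"]
            )
        except InvalidParameterError:
            vc_corr = None
        try:
            qm_corr = correlate(sub["mean_collision_number"], sub["qm_nc_per_g"])
        except InvalidParameterError:
            qm_corr = None
    return CharacterizationResult(
        table=table,
        vc_vs_protein=vc_corr,
        qm_vs_collisions=qm_corr,
        uncharacterizable=uncharacterizable,
    )
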