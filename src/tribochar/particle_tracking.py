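"""Lagrangian tracking of dilute-phase particles and wall-collision statistics.

Particles are one-way coupled to the gas: each trajectory is integrated under
Schiller-Naumann drag, gravity transverse to the pipe axis (horizontal pipe)
and, in turbulent flow, a discrete-random-walk (eddy-interaction) dispersion
model.  Wall contacts are specular reflections scaled by a restitution
coefficient; contacts whose rebound can detach the particle from the wall
(normal speed at least ``sqrt(g d_p)``) are logged as charging collisions,
shallower ones count as rolling contact.  The headline output is the mean
number of particle-wall collisions per released particle, the ``n`` of the
condenser charging model.

Coordinates: ``x`` streamwise (pipe axis, horizontal), ``z`` vertical
(gravity acts along ``-z``), ``y`` spanwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from ._errors import (
    IntegrationFailureError,
    InvalidParameterError,
    RangeWarning,
    SimulationTimeoutError,
)
from .flow_field import AIR, FlowProfile, GasProperties, PipeGeometry, build_profile

__all__ = [
    "ParticleSpec",
    "TrackingConfig",
    "CollisionSummary",
    "Condition",
    "GRAVITY",
    "drag_coefficient",
    "particle_response_time",
    "stokes_number",
    "simulate",
    "run_condition",
    "sweep",
    "TABLE_RANGES",
]

#: Standard gravity, m/s^2 (acts along -z, i.e. towards the lower pipe wall).
GRAVITY = 9.81

#: Kallio-Reeks fit constants for the wall-normal rms fluctuation profile,
#: sigma_r+ = 0.005 y+^2 / (1 + 0.002923 y+^2.128), valid up to y+ ~ 200.
#: Wall-normal kicks must vanish at the wall (real boundary layers damp
#: them), otherwise tracer-like particles are slammed into the wall at an
#: unphysical rate.
_KR_C = 0.002923
_KR_P = 2.128
_KR_YMAX = 200.0

#: Wall-normal Lagrangian timescale fit, T_L+ = 7.122 + 0.5731 y+ - 0.00129 y+^2
#: (clipped at its vertex); used by the wall-normal Ornstein-Uhlenbeck process.
_TL_A, _TL_B, _TL_C = 7.122, 0.5731, 0.00129
_TL_YMAX = _TL_B / (2.0 * _TL_C)


@njit(cache=True)
def _sigma_r_plus(yplus: float) -> float:
    yp = min(yplus, _KR_YMAX)
    return 0.005 * yp**2 / (1.0 + _KR_C * yp**_KR_P)


@njit(cache=True)
def _dsigma2_r_plus(yplus: float) -> float:
    """d(sigma_r+^2)/dy+ of the Kallio-Reeks profile (0 beyond the fit range)."""
    if yplus >= _KR_YMAX:
        return 0.0
    yp = yplus
    denom = 1.0 + _KR_C * yp**_KR_P
    f = 0.005 * yp**2 / denom
    fprime = 0.01 * yp / denom - f * _KR_C * _KR_P * yp ** (_KR_P - 1.0) / denom
    return 2.0 * f * fprime


@njit(cache=True)
def _tl_plus(yplus: float) -> float:
    yp = min(yplus, _TL_YMAX)
    return _TL_A + _TL_B * yp - _TL_C * yp**2


@njit(cache=True)
def _reichardt_uplus_s(yplus: float) -> float:
    return (1.0 / 0.41) * math.log1p(0.41 * yplus) + 7.8 * (
        1.0 - math.exp(-yplus / 11.0) - (yplus / 11.0) * math.exp(-yplus / 3.0)
    )


@njit(cache=True)
def _u_axial(
    r: float,
    radius: float,
    regime_code: int,  # 0 laminar, 1 turbulent power-law, 2 turbulent wall law
    mean_velocity: float,
    centerline: float,
    u_tau: float,
    nu: float,
    velocity_scale: float,
) -> float:
    s = r / radius
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    if regime_code == 0:
        return 2.0 * mean_velocity * (1.0 - s * s)
    if regime_code == 1:
        return centerline * (1.0 - s) ** (1.0 / 7.0)
    yplus = radius * (1.0 - s) * u_tau / nu
    return velocity_scale * _reichardt_uplus_s(yplus)


@njit(cache=True)
def _integrate_one(
    seed: np.int64,
    r0: float,
    theta0: float,
    w0: float,
    dt: float,
    t_max: float,
    radius: float,
    r_wall: float,
    length: float,
    d_p: float,
    tau_p: float,
    v_detach: float,
    rho_g: float,
    mu: float,
    g: float,
    restitution: float,
    regime_code: int,
    wall_resolved: int,
    mean_velocity: float,
    centerline: float,
    u_tau: float,
    nu: float,
    velocity_scale: float,
    sigma: float,
    eddy_len: float,
    eddy_lifetime: float,
    collect_events: int,
):
    """Integrate a single particle; returns (status, count, vi_sum, events).

    status: 0 = exited, 1 = timed out, 2 = non-finite state (error).
    Events (axial position, normal impact speed, time) are filled only when
    ``collect_events`` is set.
    """
    np.random.seed(seed)
    turbulent = regime_code > 0

    y = r0 * math.cos(theta0)
    z = r0 * math.sin(theta0)
    x = 0.0
    vx = _u_axial(r0, radius, regime_code, mean_velocity, centerline, u_tau, nu, velocity_scale)
    vy = 0.0
    vz = -w0
    upx = 0.0
    upy = 0.0
    upz = 0.0
    eddy_left = 0.0
    zeta = np.random.normal() if turbulent else 0.0

    count = 0
    vi_sum = 0.0
    cap = 64 if collect_events else 0
    ev_x = np.empty(cap)
    ev_v = np.empty(cap)
    ev_t = np.empty(cap)

    status = 1  # timed out unless it exits
    t = 0.0
    step = 0
    while t < t_max:
        step += 1
        t += dt
        r = math.hypot(y, z)

        ug_base = _u_axial(r, radius, regime_code, mean_velocity, centerline, u_tau, nu, velocity_scale)

        if turbulent:
            if eddy_left <= 0.0:
                upx = sigma * np.random.normal()
                upy = sigma * np.random.normal()
                upz = sigma * np.random.normal()
                slip0 = math.sqrt(
                    (ug_base + upx - vx) ** 2 + (upy - vy) ** 2 + (upz - vz) ** 2
                )
                arg = 1.0 - eddy_len / (tau_p * max(slip0, 1e-30))
                transit = -tau_p * math.log(arg) if arg > 0.0 else 1e30
                eddy_left = min(eddy_lifetime, transit)

        ugx = ug_base + upx
        if turbulent and wall_resolved:
            # radial fluctuation: normalized OU process with the wall-damped
            # rms profile and the inertia-weighted well-mixed drift
            rr = max(r, 1e-30)
            nry = y / rr
            nrz = z / rr
            yplus = max((radius - r) * u_tau / nu, 0.0)
            tlp = _tl_plus(yplus)
            tl = tlp * nu / (u_tau * u_tau)
            decay = math.exp(-dt / tl)
            zeta = zeta * decay + math.sqrt(1.0 - decay * decay) * np.random.normal()
            drift = u_tau * tlp * _dsigma2_r_plus(yplus) / (1.0 + tau_p / tl)
            sigma_r = min(u_tau * _sigma_r_plus(yplus), sigma)
            u_rad = sigma_r * zeta - drift  # outward positive
            # tangential eddy component damped linearly in y+ near the wall
            tang = min(0.08 * yplus * u_tau, sigma) / sigma if sigma > 0.0 else 0.0
            upr = upy * nry + upz * nrz
            ugy = (upy - upr * nry) * tang + u_rad * nry
            ugz = (upz - upr * nrz) * tang + u_rad * nrz
        else:
            ugy = upy
            ugz = upz

        slip = math.sqrt((ugx - vx) ** 2 + (ugy - vy) ** 2 + (ugz - vz) ** 2)
        rep = rho_g * slip * d_p / mu
        if rep <= 0.0:
            f = 1.0
        elif rep <= 1000.0:
            f = 1.0 + 0.15 * rep**0.687
        else:
            f = 0.44 * rep / 24.0
        tau_d = tau_p / f

        denom = 1.0 + dt / tau_d
        vx = (vx + dt * ugx / tau_d) / denom
        vy = (vy + dt * ugy / tau_d) / denom
        vz = (vz + dt * (ugz / tau_d - g)) / denom

        x += dt * vx
        y += dt * vy
        z += dt * vz

        if x >= length:  # exited before any same-step wall contact counts
            status = 0
            break

        r = math.hypot(y, z)
        if r >= r_wall:
            rb = max(r, 1e-30)
            ny = y / rb
            nz = z / rb
            vr = vy * ny + vz * nz
            if vr > 0.0:
                if vr >= v_detach:
                    count += 1
                    vi_sum += vr
                    if collect_events:
                        if count > cap:
                            new_cap = cap * 2
                            new_x = np.empty(new_cap)
                            new_v = np.empty(new_cap)
                            new_t = np.empty(new_cap)
                            new_x[:cap] = ev_x
                            new_v[:cap] = ev_v
                            new_t[:cap] = ev_t
                            ev_x, ev_v, ev_t = new_x, new_v, new_t
                            cap = new_cap
                        ev_x[count - 1] = x
                        ev_v[count - 1] = vr
                        ev_t[count - 1] = t
                vy -= (1.0 + restitution) * vr * ny
                vz -= (1.0 + restitution) * vr * nz
            r_new = 2.0 * r_wall - r
            if r_new < 0.0:
                r_new = 0.0
            elif r_new > r_wall * (1.0 - 1e-12):
                r_new = r_wall * (1.0 - 1e-12)
            scale = r_new / rb
            y *= scale
            z *= scale

        eddy_left -= dt

        if step % 512 == 0 and not (
            math.isfinite(x) and math.isfinite(vx) and math.isfinite(vz)
        ):
            status = 2
            break

    n_ev = count if collect_events else 0
    return status, count, vi_sum, ev_x[:n_ev], ev_v[:n_ev], ev_t[:n_ev]

#: Ranges covered by the surrogate training database; ``sweep`` warns outside.
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "particle_diameter": (10e-6, 600e-6),
    "particle_density": (1410.0, 7850.0),
    "pipe_diameter": (0.002, 0.006),
    "pipe_length": (0.25, 1.5),
    "air_velocity": (6.5, 36.0),
    "vertical_speed": (0.0, 1.2),
}


@dataclass(frozen=True)
class ParticleSpec:
    """Physical identity of a powder particle.

    Defaults for the elastic constants correspond to a dry plant-protein
    flour (these only enter the charging model through the Hertzian contact
    area, never the trajectories).
    """

    diameter: float  # m
    density: float  # kg/m^3
    youngs_modulus: float = 2.0e9  # Pa
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise InvalidParameterError("particle diameter and density must be positive")
        if self.youngs_modulus <= 0:
            raise InvalidParameterError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise InvalidParameterError("Poisson ratio must lie in [0, 0.5)")


@dataclass(frozen=True)
class TrackingConfig:
    """Numerical controls for one tracking run.

    ``time_step=None`` selects a step automatically from the particle
    response time, the eddy lifetime and the wall-crossing timescale;
    an explicit step is shrunk (with a warning) if it fails to resolve
    the particle response time (dt <= tau_p / 5).

    ``injection_radius_fraction`` scales the radius of the inlet disc over
    which particles are released uniformly at random (0 = on-axis release).
    Timed-out particles stay in the denominator of the mean collision number.
    """

    n_particles: int = 100
    time_step: float | None = None
    rng_seed: int = 0
    restitution: float = 1.0
    max_residence_factor: float = 50.0
    initial_vertical_speed: float = 0.0
    gravity: float = GRAVITY
    injection_radius_fraction: float = 1.0
    dispersion: str = "wall_resolved"  # or "homogeneous"

    def __post_init__(self) -> None:
        if self.dispersion not in ("wall_resolved", "homogeneous"):
            raise InvalidParameterError(
                f"unknown dispersion closure {self.dispersion!r}"
            )
        if self.n_particles < 1:
            raise InvalidParameterError("n_particles must be >= 1")
        if self.time_step is not None and self.time_step <= 0:
            raise InvalidParameterError("time_step must be positive")
        if not 0.0 < self.restitution <= 1.0:
            raise InvalidParameterError("restitution must lie in (0, 1]")
        if self.max_residence_factor < 1.0:
            raise InvalidParameterError("max_residence_factor must be >= 1")
        if self.initial_vertical_speed < 0:
            raise InvalidParameterError("initial_vertical_speed must be >= 0")
        if not 0.0 <= self.injection_radius_fraction <= 1.0:
            raise InvalidParameterError("injection_radius_fraction must lie in [0, 1]")


@dataclass
class CollisionSummary:
    """Per-condition particle-wall collision statistics."""

    mean_collision_number: float
    mean_normal_impact_speed: float
    per_particle_counts: np.ndarray
    n_released: int
    n_exited: int
    n_timed_out: int
    events: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.events is None:
            self.events = pd.DataFrame(
                columns=["axial_position", "normal_impact_speed", "time"]
            )

    @property
    def collision_count_sem(self) -> float:
        """Monte-Carlo standard error of the mean collision number."""
        counts = np.asarray(self.per_particle_counts, dtype=float)
        if counts.size < 2:
            return float("nan")
        return float(counts.std(ddof=1) / math.sqrt(counts.size))


def drag_coefficient(reynolds_p) -> float | np.ndarray:
    """Schiller-Naumann drag coefficient of a rigid sphere.

    ``Cd = 24/Re_p * (1 + 0.15 Re_p^0.687)`` up to Re_p = 1000, constant
    0.44 beyond; the two branches are nearly continuous at the switch.
    """
    rep = np.asarray(reynolds_p, dtype=float)
    if np.any(rep <= 0):
        raise InvalidParameterError("particle Reynolds number must be positive")
    cd = np.where(
        rep <= 1000.0,
        24.0 / rep * (1.0 + 0.15 * rep**0.687),
        0.44,
    )
    return cd if cd.ndim else float(cd)


def particle_response_time(spec: ParticleSpec, gas: GasProperties) -> float:
    """Stokes response (relaxation) time ``tau_p = rho_p d_p^2 / (18 mu)``, s."""
    return spec.density * spec.diameter**2 / (18.0 * gas.dynamic_viscosity)


def stokes_number(
    spec: ParticleSpec, gas: GasProperties, flow: FlowProfile
) -> tuple[float, str]:
    """Stokes number ``tau_p / tau_L`` and its dispersion regime.

    Regimes follow the conventional thresholds: low (Stk < 1, tracer-like),
    moderate (1 <= Stk < 10, near-wall trapping), high (Stk >= 10,
    ballistic crossing).  Stk = 1 is classified as moderate.
    """
    if not math.isfinite(flow.integral_timescale):
        raise InvalidParameterError(
            "Stokes regime undefined without turbulence timescale (laminar flow)"
        )
    stk = particle_response_time(spec, gas) / flow.integral_timescale
    if stk < 1.0:
        regime = "low"
    elif stk < 10.0:
        regime = "moderate"
    else:
        regime = "high"
    return stk, regime


def _auto_time_step(
    tau_p: float, flow: FlowProfile, geometry: PipeGeometry, config: TrackingConfig
) -> float:
    """Pick a step resolving drag response, eddies and wall crossings."""
    candidates = [tau_p / 5.0]
    if flow.regime == "turbulent":
        candidates.append(flow.eddy_lifetime / 3.0)
        if config.dispersion == "wall_resolved":
            # resolve the near-wall Lagrangian timescale of the radial process
            tl_wall = _TL_A * flow.kinematic_viscosity / flow.friction_velocity**2
            candidates.append(tl_wall / 3.0)
    # transverse speed scale: fluctuations, injection speed, gravity over one radius
    v_ref = max(
        flow.fluctuation_rms,
        config.initial_vertical_speed,
        math.sqrt(2.0 * config.gravity * geometry.radius) if config.gravity > 0 else 0.0,
        1e-6,
    )
    candidates.append(geometry.radius / (10.0 * v_ref))
    # resolve the axial transit
    candidates.append(geometry.length / flow.mean_velocity / 100.0)
    return min(candidates)


def simulate(
    spec: ParticleSpec,
    flow: FlowProfile,
    geometry: PipeGeometry,
    gas: GasProperties,
    config: TrackingConfig,
    collect_events: bool = True,
) -> CollisionSummary:
    """Track ``config.n_particles`` seeded particles through the pipe.

    Particles are released at ``x = 0`` uniformly over the inlet cross
    section with the local gas velocity as initial axial velocity and
    ``-initial_vertical_speed`` as initial vertical velocity.  A wall
    contact (center-to-axis distance >= R - d_p/2) reflects the normal
    velocity times the restitution coefficient, preserves the tangential
    component, and — when the rebound clears one particle radius — logs the
    pre-impact outward normal speed as a charging collision.  A particle
    terminates on axial exit or after
    ``max_residence_factor * length / mean_velocity`` seconds.
    """
    rng = np.random.default_rng(config.rng_seed)
    radius = geometry.radius
    r_wall = radius - 0.5 * spec.diameter
    if r_wall <= 0:
        raise InvalidParameterError("particle diameter exceeds the pipe diameter")

    tau_p = particle_response_time(spec, gas)
    # detachment criterion: a rebound shallower than one particle radius
    # (v_n < sqrt(2 g a)) cannot separate the particle from the wall — it is
    # rolling/sliding contact, not a discrete charging impact
    v_detach = (
        math.sqrt(2.0 * config.gravity * 0.5 * spec.diameter)
        if config.gravity > 0
        else 0.0
    )
    dt = _auto_time_step(tau_p, flow, geometry, config)
    if config.time_step is not None:
        if config.time_step > tau_p / 5.0:
            warnings.warn(
                f"time_step {config.time_step:.3g}s does not resolve the particle "
                f"response time; shrunk to {tau_p / 5.0:.3g}s",
                RangeWarning,
                stacklevel=2,
            )
            dt = tau_p / 5.0
        else:
            dt = config.time_step
    t_max = config.max_residence_factor * geometry.length / flow.mean_velocity

    n = config.n_particles
    turbulent = flow.regime == "turbulent"
    regime_code = 0 if not turbulent else (1 if flow.profile_model == "power_law" else 2)

    # --- injection (uniform over a disc, seeded) -------------------------
    r0_max = r_wall * config.injection_radius_fraction
    r0 = r0_max * np.sqrt(rng.random(n))
    theta0 = 2.0 * math.pi * rng.random(n)
    # independent per-particle integration streams derived from the run seed
    particle_seeds = np.random.SeedSequence(config.rng_seed).generate_state(n).astype(
        np.int64
    )

    counts = np.zeros(n, dtype=np.int64)
    exited = np.zeros(n, dtype=bool)
    vi_total = 0.0
    ev_x: list[np.ndarray] = []
    ev_v: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []

    for i in range(n):
        status, count, vi_sum, px, pv, pt = _integrate_one(
            particle_seeds[i],
            float(r0[i]),
            float(theta0[i]),
            config.initial_vertical_speed,
            dt,
            t_max,
            radius,
            r_wall,
            geometry.length,
            spec.diameter,
            tau_p,
            v_detach,
            gas.density,
            gas.dynamic_viscosity,
            config.gravity,
            config.restitution,
            regime_code,
            1 if (turbulent and config.dispersion == "wall_resolved") else 0,
            flow.mean_velocity,
            flow.centerline_velocity,
            flow.friction_velocity,
            flow.kinematic_viscosity,
            flow.velocity_scale,
            flow.fluctuation_rms,
            flow.eddy_length,
            flow.eddy_lifetime,
            1 if collect_events else 0,
        )
        if status == 2:
            raise IntegrationFailureError(
                f"non-finite state for particle {i} (seed {particle_seeds[i]})"
            )
        counts[i] = count
        exited[i] = status == 0
        vi_total += vi_sum
        if collect_events and count:
            ev_x.append(px)
            ev_v.append(pv)
            ev_t.append(pt)

    n_exited = int(exited.sum())
    n_timed_out = n - n_exited
    if n_exited == 0:
        raise SimulationTimeoutError(
            f"all {n} particles timed out after {t_max:.3g} s "
            f"(dt = {dt:.3g} s, mean counts = {counts.mean():.2f})"
        )

    total_events = int(counts.sum())
    mean_vi = vi_total / total_events if total_events else 0.0
    if collect_events and ev_x:
        events = pd.DataFrame(
            {
                "axial_position": np.concatenate(ev_x),
                "normal_impact_speed": np.concatenate(ev_v),
                "time": np.concatenate(ev_t),
            }
        )
    else:
        events = None

    return CollisionSummary(
        mean_collision_number=float(counts.mean()),
        mean_normal_impact_speed=mean_vi,
        per_particle_counts=counts,
        n_released=n,
        n_exited=n_exited,
        n_timed_out=n_timed_out,
        events=events,
    )


@dataclass(frozen=True)
class Condition:
    """One fully specified tracking condition (the surrogate's input space)."""

    particle_diameter: float  # m
    particle_density: float  # kg/m^3
    pipe_length: float  # m
    pipe_diameter: float  # m
    air_velocity: float  # m/s
    vertical_speed: float = 0.0  # m/s, injection wall-normal speed
    regime: str = "auto"

    def as_dict(self) -> dict[str, float | str]:
        return {
            "particle_diameter": self.particle_diameter,
            "particle_density": self.particle_density,
            "pipe_length": self.pipe_length,
            "pipe_diameter": self.pipe_diameter,
            "air_velocity": self.air_velocity,
            "vertical_speed": self.vertical_speed,
            "regime": self.regime,
        }


def run_condition(
    condition: Condition,
    gas: GasProperties = AIR,
    config: TrackingConfig | None = None,
    collect_events: bool = False,
) -> CollisionSummary:
    """Build geometry/flow from a :class:`Condition` and run :func:`simulate`."""
    if config is None:
        config = TrackingConfig()
    config = replace(config, initial_vertical_speed=condition.vertical_speed)
    geometry = PipeGeometry(condition.pipe_length, condition.pipe_diameter)
    flow = build_profile(geometry, gas, condition.air_velocity, condition.regime)
    spec = ParticleSpec(condition.particle_diameter, condition.particle_density)
    return simulate(spec, flow, geometry, gas, config, collect_events=collect_events)


def sweep(
    conditions: Sequence[Condition | Mapping],
    gas: GasProperties = AIR,
    config: TrackingConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run a parameter study: one seeded tracking run per condition.

    Each grid point uses ``base_seed + index`` so any single point can be
    reproduced by a direct :func:`run_condition` call.  A failing point is
    flagged in the ``error`` column and the sweep continues.
    """
    if config is None:
        config = TrackingConfig()
    rows = []
    for i, cond in enumerate(conditions):
        if isinstance(cond, Mapping):
            cond = Condition(**cond)
        _warn_outside_ranges(cond)
        row: dict = dict(cond.as_dict())
        row["seed"] = base_seed + i
        cfg = replace(config, rng_seed=base_seed + i)
        try:
            summary = run_condition(cond, gas=gas, config=cfg)
        except Exception as exc:  # noqa: BLE001 - per-point isolation is the contract
            row.update(
                mean_collision_number=np.nan,
                mean_normal_impact_speed=np.nan,
                collision_count_sem=np.nan,
                n_exited=0,
                n_timed_out=0,
                error=f"{type(exc).__name__}: {exc}",
            )
        else:
            row.update(
                mean_collision_number=summary.mean_collision_number,
                mean_normal_impact_speed=summary.mean_normal_impact_speed,
                collision_count_sem=summary.collision_count_sem,
                n_exited=summary.n_exited,
                n_timed_out=summary.n_timed_out,
                error="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _warn_outside_ranges(cond: Condition) -> None:
    for name, (lo, hi) in TABLE_RANGES.items():
        value = getattr(cond, name)
        if not lo <= value <= hi:
            warnings.warn(
                f"{name} = {value:g} outside the database range [{lo:g}, {hi:g}]",
                RangeWarning,
                stacklevel=3,
            )
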