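"""Lagrangian tracker: drag law, timescales, collision statistics, sweeps."""

import warnings

import numpy as np
import pytest

from tribochar._errors import InvalidParameterError, RangeWarning
from tribochar.flow_field import AIR, GasProperties, PipeGeometry, build_profile
from tribochar.particle_tracking import (
    Condition,
    ParticleSpec,
    TrackingConfig,
    drag_coefficient,
    particle_response_time,
    run_condition,
    simulate,
    stokes_number,
    sweep,
)


class TestDragCoefficient:
    def test_stokes_correction_at_unity(self):
        assert drag_coefficient(1.0) == pytest.approx(24.0 * 1.15, rel=1e-12)

    def test_newton_branch(self):
        assert drag_coefficient(10_000.0) == 0.44

    def test_branch_continuity(self):
        left = drag_coefficient(1000.0)
        assert left == pytest.approx(0.4385, abs=1e-3)
        assert abs(left - 0.44) < 0.01

    def test_monotone_decreasing_up_to_newton(self):
        rep = np.logspace(-2, 3, 50)
        cd = drag_coefficient(rep)
        assert np.all(np.diff(cd) < 0)

    def test_invalid_rejected(self):
        with pytest.raises(InvalidParameterError):
            drag_coefficient(0.0)


class TestResponseTimeAndStokes:
    def test_response_time_hand_value(self):
        gas = GasProperties(dynamic_viscosity=1.8e-5)
        spec = ParticleSpec(100e-6, 1440.0)
        assert particle_response_time(spec, gas) == pytest.approx(
            1440 * (100e-6) ** 2 / (18 * 1.8e-5), rel=1e-12
        )
        assert particle_response_time(spec, gas) == pytest.approx(0.0444, rel=1e-2)

    def test_quadratic_diameter_and_linear_density_scaling(self):
        base = particle_response_time(ParticleSpec(50e-6, 1440.0), AIR)
        assert particle_response_time(ParticleSpec(200e-6, 1440.0), AIR) == pytest.approx(
            16 * base, rel=1e-12
        )
        assert particle_response_time(ParticleSpec(50e-6, 2880.0), AIR) == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_unit_ratio_is_moderate(self, headline_flow):
        """Stk = 1 at tau_p = tau_L, classified moderate (tie-break)."""
        tau_l = headline_flow.integral_timescale
        d = np.sqrt(tau_l * 18 * AIR.dynamic_viscosity / 1440.0)
        stk, regime = stokes_number(ParticleSpec(d, 1440.0), AIR, headline_flow)
        assert stk == pytest.approx(1.0, rel=1e-9)
        assert regime == "moderate"

    def test_regimes_at_headline_condition(self, headline_flow):
        """10-um particles are tracer-like, 300-um ones ballistic."""
        assert stokes_number(ParticleSpec(10e-6, 1440.0), AIR, headline_flow)[1] == "low"
        assert (
            stokes_number(ParticleSpec(300e-6, 1440.0), AIR, headline_flow)[1] == "high"
        )

    def test_monotone_in_diameter(self, headline_flow):
        stks = [
            stokes_number(ParticleSpec(d, 1440.0), AIR, headline_flow)[0]
            for d in (10e-6, 60e-6, 300e-6)
        ]
        assert stks[0] < stks[1] < stks[2]

    def test_laminar_flow_rejected(self):
        geom = PipeGeometry(1.0, 4.76e-3)
        flow = build_profile(geom, AIR, 6.5, regime="laminar")
        with pytest.raises(InvalidParameterError, match="Stokes regime undefined"):
            stokes_number(ParticleSpec(60e-6, 1440.0), AIR, flow)


class TestSimulate:
    def test_axis_release_no_gravity_laminar_never_collides(self):
        """No transverse force and an on-axis release leave r = 0 forever."""
        geom = PipeGeometry(0.5, 4.76e-3)
        flow = build_profile(geom, AIR, 6.5, regime="laminar")
        cfg = TrackingConfig(
            n_particles=10, gravity=0.0, injection_radius_fraction=0.0, rng_seed=3
        )
        summary = simulate(ParticleSpec(60e-6, 1440.0), flow, geom, AIR, cfg)
        assert summary.mean_collision_number == 0.0
        assert summary.n_exited == 10

    def test_seeded_determinism(self, headline_geometry, headline_flow):
        cfg = TrackingConfig(n_particles=40, rng_seed=11)
        spec = ParticleSpec(61.7e-6, 1440.0)
        a = simulate(spec, headline_flow, headline_geometry, AIR, cfg)
        b = simulate(spec, headline_flow, headline_geometry, AIR, cfg)
        np.testing.assert_array_equal(a.per_particle_counts, b.per_particle_counts)
        assert a.mean_normal_impact_speed == b.mean_normal_impact_speed

    def test_exit_accounting(self, headline_geometry, headline_flow):
        cfg = TrackingConfig(n_particles=50, rng_seed=5)
        s = simulate(ParticleSpec(25e-6, 1440.0), headline_flow, headline_geometry, AIR, cfg)
        assert s.n_exited + s.n_timed_out == s.n_released == 50
        assert s.mean_collision_number == pytest.approx(
            s.per_particle_counts.sum() / 50, rel=1e-12
        )

    def test_event_log_consistency(self, headline_geometry, headline_flow):
        cfg = TrackingConfig(n_particles=30, rng_seed=2)
        s = simulate(
            ParticleSpec(100e-6, 1440.0), headline_flow, headline_geometry, AIR, cfg,
            collect_events=True,
        )
        assert len(s.events) == s.per_particle_counts.sum()
        assert (s.events.normal_impact_speed > 0).all()
        assert s.events.axial_position.between(0, 1.0).all()
        assert s.mean_normal_impact_speed == pytest.approx(
            s.events.normal_impact_speed.mean(), rel=1e-9
        )

    def test_terminal_velocity_oracle(self):
        """A settling particle reaches the Schiller-Naumann terminal velocity.

        Independent oracle: fixed-point solve of v = tau_p*g/f(Re_p(v)).
        The first wall impact in a wide pipe with negligible axial flow
        happens at terminal speed.
        """
        spec = ParticleSpec(61.7e-6, 1440.0)
        tau_p = particle_response_time(spec, AIR)
        g = 9.81
        v = tau_p * g
        for _ in range(200):
            rep = AIR.density * v * spec.diameter / AIR.dynamic_viscosity
            f = 1.0 + 0.15 * rep**0.687 if rep <= 1000 else 0.44 * rep / 24.0
            v = tau_p * g / f
        geom = PipeGeometry(length=1.0, inner_diameter=0.1)
        flow = build_profile(geom, AIR, 0.5, regime="laminar")
        cfg = TrackingConfig(
            n_particles=1,
            rng_seed=0,
            injection_radius_fraction=0.0,
            time_step=tau_p / 20,
            # the settled particle creeps out through the slow near-wall layer
            max_residence_factor=5000.0,
        )
        s = simulate(spec, flow, geom, AIR, cfg, collect_events=True)
        assert len(s.events) >= 1
        assert s.events.normal_impact_speed.iloc[0] == pytest.approx(v, rel=0.01)

    def test_tracer_limit(self, headline_geometry, headline_flow):
        """Vanishingly small particles collide no more than 25-um ones."""
        counts = {}
        for d in (5e-6, 25e-6):
            vals = [
                simulate(
                    ParticleSpec(d, 1440.0), headline_flow, headline_geometry, AIR,
                    TrackingConfig(rng_seed=s), collect_events=False,
                ).mean_collision_number
                for s in range(2)
            ]
            counts[d] = np.mean(vals)
        assert counts[5e-6] <= counts[25e-6]

    def test_oversized_particle_rejected(self):
        geom = PipeGeometry(1.0, 4.76e-3)
        flow = build_profile(geom, AIR, 8.4, regime="turbulent")
        with pytest.raises(InvalidParameterError):
            simulate(ParticleSpec(5e-3, 1440.0), flow, geom, AIR, TrackingConfig())

    def test_coarse_time_step_shrunk_with_warning(self, headline_geometry, headline_flow):
        spec = ParticleSpec(25e-6, 1440.0)
        cfg = TrackingConfig(n_particles=5, time_step=1.0, rng_seed=1)
        with pytest.warns(RangeWarning, match="does not resolve"):
            simulate(spec, headline_flow, headline_geometry, AIR, cfg)


class TestSweep:
    BASE = dict(
        particle_density=1440.0, pipe_length=1.0, pipe_diameter=4.76e-3,
        air_velocity=8.4, regime="turbulent",
    )

    def test_singleton_reproduces_simulate(self):
        cond = Condition(particle_diameter=61.7e-6, **self.BASE)
        cfg = TrackingConfig(n_particles=30)
        table = sweep([cond], config=cfg, base_seed=9)
        direct = run_condition(cond, config=TrackingConfig(n_particles=30, rng_seed=9))
        assert table.loc[0, "mean_collision_number"] == direct.mean_collision_number
        assert table.loc[0, "mean_normal_impact_speed"] == direct.mean_normal_impact_speed

    def test_failing_point_is_flagged_and_sweep_continues(self):
        good = Condition(particle_diameter=61.7e-6, **self.BASE)
        bad = Condition(particle_diameter=5e-3, **self.BASE)  # exceeds the bore
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sweep([good, bad, good], config=TrackingConfig(n_particles=10))
        assert table.loc[0, "error"] == "" and table.loc[2, "error"] == ""
        assert "InvalidParameterError" in table.loc[1, "error"]
        assert np.isnan(table.loc[1, "mean_collision_number"])

    def test_out_of_range_condition_warns(self):
        tiny = Condition(particle_diameter=1e-6, **self.BASE)
        with pytest.warns(RangeWarning, match="particle_diameter"):
            sweep([tiny], config=TrackingConfig(n_particles=2))
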