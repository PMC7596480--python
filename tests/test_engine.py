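"""Ensemble dynamics: stepping, absorption, conservation, reproducibility."""

from dataclasses import replace

import numpy as np
import pytest

from tubetransit.engine import (SimulationConfig, arrival_fraction, auto_dt,
                                run_simulation, step_ensemble)
from tubetransit.errors import ValidationError
from tubetransit.geometry import Geometry
from tubetransit.physics import ForceSpec, InteractionSpec, ParticleSpec
from tubetransit.state import ACTIVE, EnsembleState

MM = 1e-3


def free_space_state(n, x_mm=50.0):
    """Ensemble far from any wall of a very wide straight channel."""
    pos = np.full((n, 3), 0.0)
    pos[:, 0] = x_mm * MM
    return EnsembleState(time=0.0, positions=pos,
                         status=np.full(n, ACTIVE, dtype=np.uint8),
                         absorption_time=np.full(n, np.nan))


def wide_channel_config(**kwargs):
    geo = Geometry(mode="straight_channel", tube_length=50.0,
                   tube_radius=10.0, cavity_side=30.0)
    defaults = dict(geometry=geo, particles=ParticleSpec(count=100),
                    t_end=600.0, record_every=60.0, seed=0)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestStepEnsemble:
    def test_no_dynamics_means_no_motion(self):
        config = wide_channel_config(d_scale=0.0)
        state = free_space_state(50)
        rng = np.random.default_rng(0)
        new = step_ensemble(state, config, rng, dt=1.0)
        np.testing.assert_array_equal(new.positions, state.positions)

    def test_pure_drift_advances_mu_f_dt(self):
        # vanishing temperature kills diffusion but leaves the Stokes
        # mobility finite, so the step is pure deterministic drift
        from tubetransit.physics import Medium
        cold = Medium(name="cold", temperature=1e-15,
                      dynamic_viscosity=1.86e-5, mean_free_path=0.0)
        force = ForceSpec(mode="constant", direction="+x",
                          magnitude_model="explicit", magnitude=1e-16)
        config = wide_channel_config(medium=cold, force=force, slip=False)
        from tubetransit.engine import effective_mobility
        mu = effective_mobility(config)
        state = free_space_state(20)
        new = step_ensemble(state, config, np.random.default_rng(0), dt=1.0)
        dx = new.positions[:, 0] - state.positions[:, 0]
        np.testing.assert_allclose(dx, mu * 1e-16 * 1.0, rtol=1e-3)
        assert np.allclose(new.positions[:, 1:], state.positions[:, 1:],
                           atol=1e-9)

    def test_free_space_msd_matches_brownian_motion(self):
        config = wide_channel_config(particles=ParticleSpec(count=10000))
        from tubetransit.engine import effective_diffusion
        D = effective_diffusion(config)
        dt = 1.0
        n_steps = 100
        state = free_space_state(10000)
        start = state.positions.copy()
        rng = np.random.default_rng(42)
        for _ in range(n_steps):
            state = step_ensemble(state, config, rng, dt=dt)
        disp2 = np.sum((state.positions - start) ** 2, axis=1)
        t = n_steps * dt
        expected = 6 * D * t
        se = expected * np.sqrt(6) / 3 / np.sqrt(10000)
        assert abs(disp2.mean() - expected) < 3 * se

    def test_absorbed_particles_never_move(self):
        config = wide_channel_config()
        state = free_space_state(10)
        state.status[3] = 1
        state.absorption_time[3] = 5.0
        new = step_ensemble(state, config, np.random.default_rng(1), dt=1.0)
        np.testing.assert_array_equal(new.positions[3], state.positions[3])
        assert new.absorption_time[3] == 5.0


class TestRunSimulation:
    def test_zero_horizon_gives_single_zero_point(self):
        config = SimulationConfig(particles=ParticleSpec(count=10),
                                  t_end=0.0, seed=1)
        curve, state = run_simulation(config)
        assert len(curve.times) == 1
        assert curve.fractions[0] == 0.0
        assert state.n_active == 10

    def test_conservation_and_monotone_curve(self, oracle_config):
        curve, state = run_simulation(replace(oracle_config, seed=2))
        assert state.n_active + state.n_absorbed == state.n_total
        assert np.all(np.diff(curve.fractions) >= 0)
        assert curve.fractions[0] == 0.0
        assert 0 <= curve.fractions[-1] <= 1
        # absorbed bookkeeping is consistent
        absorbed = state.status == 1
        assert np.all(np.isfinite(state.absorption_time[absorbed]))
        assert np.all(state.absorption_time[absorbed] <= curve.times[-1])
        assert np.all(np.isnan(state.absorption_time[~absorbed]))

    def test_bitwise_reproducibility_fast_path(self, oracle_config):
        a, sa = run_simulation(oracle_config)
        b, sb = run_simulation(oracle_config)
        np.testing.assert_array_equal(a.fractions, b.fractions)
        np.testing.assert_array_equal(sa.positions, sb.positions)

    def test_bitwise_reproducibility_interacting_path(self):
        config = SimulationConfig(
            particles=ParticleSpec(count=32, charge=0.5),
            interaction=InteractionSpec(enabled=True, strength=1e-25),
            d_scale=8.0, t_end=120.0, record_every=60.0, seed=7)
        a, sa = run_simulation(config)
        b, sb = run_simulation(config)
        np.testing.assert_array_equal(a.fractions, b.fractions)
        np.testing.assert_array_equal(sa.positions, sb.positions)

    def test_different_seeds_differ(self, oracle_config):
        a, _ = run_simulation(replace(oracle_config, seed=1))
        b, _ = run_simulation(replace(oracle_config, seed=2))
        assert not np.array_equal(a.fractions, b.fractions)

    def test_zero_charge_equals_interactions_disabled(self, fixture_configs):
        on = fixture_configs["zero_charge"]
        off = replace(on, interaction=replace(on.interaction, enabled=False))
        curve_on, state_on = run_simulation(on)
        curve_off, state_off = run_simulation(off)
        np.testing.assert_array_equal(curve_on.fractions, curve_off.fractions)
        np.testing.assert_array_equal(state_on.positions, state_off.positions)

    def test_invalid_config_rejected_before_stepping(self):
        config = SimulationConfig(t_end=100.0, record_every=600.0, seed=0)
        with pytest.raises(ValidationError, match="record_every"):
            run_simulation(config)

    def test_auto_dt_rule(self):
        config = SimulationConfig(seed=0)
        from tubetransit.engine import effective_diffusion
        cap = 0.2 * config.geometry.tube_radius * MM
        assert auto_dt(config) == pytest.approx(
            cap * cap / (2 * effective_diffusion(config)))

    def test_snapshots_cover_record_grid(self, oracle_config):
        config = replace(oracle_config,
                         particles=ParticleSpec(count=50), t_end=180.0)
        curve, state, snaps = run_simulation(config, return_snapshots=True)
        assert len(snaps) == len(curve.times)
        assert snaps[0][0] == 0.0


class TestArrivalCurve:
    def test_step_interpolation_and_bounds(self, oracle_config):
        curve, _ = run_simulation(oracle_config)
        assert arrival_fraction(curve, 0.0) == 0.0
        assert arrival_fraction(curve, curve.times[-1]) == curve.fractions[-1]
        # step interpolation uses the largest recorded time <= t
        assert arrival_fraction(curve, 90.0) == curve.fractions[1]
        with pytest.raises(ValueError, match="outside"):
            arrival_fraction(curve, curve.times[-1] + 1.0)
        with pytest.raises(ValueError, match="outside"):
            arrival_fraction(curve, -1.0)

    def test_monotone_queries(self, oracle_config):
        curve, _ = run_simulation(oracle_config)
        ts = np.linspace(0, curve.times[-1], 37)
        vals = [arrival_fraction(curve, t) for t in ts]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
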