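"""Scenario matrix, scalar calibration, and in-study worked summaries."""

from dataclasses import replace

import numpy as np
import pytest

from tubetransit.engine import SimulationConfig
from tubetransit.errors import CalibrationError, ValidationError
from tubetransit.oracle import series_arrival_pure_diffusion
from tubetransit.physics import ParticleSpec
from tubetransit.scenarios import (bisect_monotone, calibrate_scalar,
                                   derive_seed, paper_scenarios,
                                   run_scenario_table, scenario_by_label,
                                   shell_thickness, spreading_frequency)


@pytest.fixture(scope="module")
def base():
    return SimulationConfig(seed=0)


class TestPaperScenarios:
    def test_full_matrix_of_nine(self, base):
        scenarios = paper_scenarios(base)
        assert len(scenarios) == 9
        labels = {s.label for s in scenarios}
        assert labels == {"force:none", "force:+x", "force:-x",
                          "size:20nm", "size:200nm", "size:2000nm",
                          "charge:0", "charge:0.1", "charge:1"}

    def test_size_sweep_differs_only_in_diameter(self, base):
        scenarios = paper_scenarios(base)
        sizes = [scenario_by_label(scenarios, f"size:{d}nm")
                 for d in ("20", "200", "2000")]
        ref = sizes[1].config
        for s in sizes:
            cfg = s.config
            assert replace(cfg, particles=replace(
                cfg.particles, diameter=200.0)) == ref

    def test_force_directions_and_magnitude_model(self, base):
        scenarios = paper_scenarios(base, force_scale=0.3)
        fwd = scenario_by_label(scenarios, "force:+x").config.force
        bwd = scenario_by_label(scenarios, "force:-x").config.force
        assert fwd.direction == "+x" and bwd.direction == "-x"
        assert fwd.magnitude_model == bwd.magnitude_model == "gravity"
        assert fwd.scale == bwd.scale == 0.3
        none = scenario_by_label(scenarios, "force:none").config.force
        assert none.mode == "none"

    def test_zero_charge_scenario_is_flagged_as_interaction_free(self, base):
        scenarios = paper_scenarios(base)
        zc = scenario_by_label(scenarios, "charge:0")
        assert zc.config.interaction.enabled
        assert zc.config.particles.charge == 0.0
        assert zc.free_scalar_binding is None

    def test_interacting_scenarios_use_reduced_count(self, base):
        scenarios = paper_scenarios(base)
        assert scenario_by_label(scenarios,
                                 "charge:0.1").config.particles.count == 256
        assert scenario_by_label(scenarios,
                                 "size:200nm").config.particles.count == 1000


class TestBisection:
    def test_target_at_midpoint_returns_quickly(self):
        calls = []

        def f(x):
            calls.append(x)
            return x

        x, fx, evals = bisect_monotone(f, 0.0, 2.0, target=1.0, f_tol=1e-9)
        assert x == pytest.approx(1.0)
        assert evals <= 3

    def test_non_monotone_toy_raises_descriptive_error(self):
        with pytest.raises(CalibrationError, match="monotone"):
            bisect_monotone(lambda x: -(x - 1.0) ** 2 + 2.0 + 0.1 * x,
                            0.0, 2.0, target=1.0, f_tol=1e-6)

    def test_unattainable_target_raises(self):
        with pytest.raises(CalibrationError, match="attainable"):
            bisect_monotone(lambda x: x, 0.0, 1.0, target=5.0, f_tol=1e-6)

    def test_recovers_known_diffusion_from_oracle_target(self):
        # generate F* from the closed-form oracle at a known D*, then
        # invert it by bisection from a decade-wide bracket
        D_star = 3e-10
        L, t = 4e-3, 10800.0
        target = series_arrival_pure_diffusion(D_star, L, t)

        def f(D):
            return series_arrival_pure_diffusion(D, L, t)

        x, fx, _ = bisect_monotone(f, D_star / 10, D_star * 10,
                                   target=target, f_tol=0.0, x_rtol=1e-3,
                                   log_scale=True)
        assert abs(x - D_star) / D_star < 0.01

    def test_calibrate_scalar_validates_inputs(self, base):
        scenarios = paper_scenarios(base)
        with pytest.raises(ValidationError, match="scalar"):
            calibrate_scalar(scenarios[0], "not_a_scalar", 0.2)
        with pytest.raises(ValidationError, match="target"):
            calibrate_scalar(scenarios[0], "global_D_scale", 1.5)


class TestScenarioTable:
    def test_table_runs_and_captures_row_errors(self, base):
        quick = replace(base, t_end=120.0, record_every=60.0, d_scale=8.0)
        scenarios = paper_scenarios(quick)
        small = []
        for label in ("force:none", "size:2000nm"):
            s = scenario_by_label(scenarios, label)
            small.append(replace(s, config=replace(
                s.config, particles=replace(s.config.particles, count=40))))
        # a deliberately broken row: record grid longer than the horizon
        bad = replace(small[0], label="broken",
                      config=replace(small[0].config, t_end=30.0))
        table = run_scenario_table(small + [bad], n_seeds=2, base_seed=1)
        frame = table.frame
        assert list(frame["label"]) == ["force:none", "size:2000nm",
                                        "broken"]
        good = frame[frame["label"] != "broken"]
        assert good["fraction_180min"].between(0, 1).all()
        assert (good["error"] == "").all()
        broken = frame[frame["label"] == "broken"].iloc[0]
        assert np.isnan(broken["fraction_180min"])
        assert "record_every" in broken["error"]
        assert table.fraction("size:2000nm") <= 1.0

    def test_derive_seed_is_stable_and_bounded(self):
        a = derive_seed(1, "force:none", 0)
        b = derive_seed(1, "force:none", 0)
        c = derive_seed(1, "force:none", 1)
        assert a == b != c
        assert 0 <= a < 2 ** 31


class TestWorkedSummaries:
    def test_shell_thickness_from_hydrodynamic_diameters(self):
        # core 265.2 nm, shelled 338.5 nm -> 36.65, printed as 36.7
        t = shell_thickness(265.2, 338.5)
        assert t == pytest.approx(36.65, abs=1e-10)
        assert round(t, 1) == 36.7

    def test_shell_thickness_edge_cases(self):
        assert shell_thickness(100.0, 100.0) == 0.0
        with pytest.raises(ValidationError, match="total_diameter"):
            shell_thickness(100.0, 90.0)

    def test_spreading_frequency_four_of_six(self):
        r = spreading_frequency(4, 6)
        assert r.percent == 66.7
        assert r.ci_low_percent < 66.7 < r.ci_high_percent
        # exact Clopper-Pearson bounds for 4/6
        from scipy.stats import beta
        assert r.ci_low_percent == pytest.approx(
            100 * beta.ppf(0.025, 4, 3), abs=0.05)
        assert r.ci_high_percent == pytest.approx(
            100 * beta.ppf(0.975, 5, 2), abs=0.05)

    @pytest.mark.parametrize("k,n,pct", [(0, 6, 0.0), (6, 6, 100.0)])
    def test_spreading_frequency_degenerate_counts(self, k, n, pct):
        r = spreading_frequency(k, n)
        assert r.percent == pct

    def test_spreading_frequency_validation(self):
        with pytest.raises(ValidationError):
            spreading_frequency(7, 6)
        with pytest.raises(ValidationError):
            spreading_frequency(0, 0)
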