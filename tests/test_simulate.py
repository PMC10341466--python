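"""Integration, convergence diagnostics, sweeps and the sampler."""

import numpy as np
import pytest

from fraudgame.game_model import MixedState, validate_parameters
from fraudgame.replicator import DynamicsMode
from fraudgame.simulate import (
    MetricSpec,
    ScenarioConfig,
    converged_state,
    integrate,
    parameter_sweep,
    parse_metric,
    run_scenario,
    sample_valid_parameters,
    scenario_config,
    scenario_parameters,
    time_to_threshold,
)
from fraudgame.stability import StabilityClass, classify, condition_flags

CORNERS = {
    "E1": (0, 0, 0), "E2": (1, 0, 0), "E3": (0, 1, 0), "E4": (0, 0, 1),
    "E5": (1, 1, 0), "E6": (1, 0, 1), "E7": (0, 1, 1), "E8": (1, 1, 1),
}


class TestIntegration:
    @pytest.mark.parametrize("preset,target", [(1, (0, 0, 0)), (2, (0, 0, 1)),
                                               (3, (1, 0, 1))])
    def test_scenario_endpoints(self, preset, target):
        traj = integrate(scenario_config(preset))
        assert traj.final_state.as_tuple() == pytest.approx(target, abs=0.01)

    def test_corner_start_stays_put(self, scenario3):
        config = ScenarioConfig(params=scenario3, initial_state=MixedState(1, 0, 1))
        traj = integrate(config)
        assert np.all(traj.states == traj.states[0])

    def test_dense_output_and_containment(self, scenario1):
        traj = integrate(scenario_config(1))
        assert len(traj.times) >= 200
        assert traj.times[0] == 0.0 and np.all(np.diff(traj.times) > 0)
        assert np.all((traj.states >= 0.0) & (traj.states <= 1.0))
        assert traj.states[0] == pytest.approx((0.8, 0.5, 0.2))

    def test_tolerance_robustness(self):
        """Halving integrator tolerances leaves preset endpoints fixed."""
        for preset in (1, 2, 3):
            base = scenario_config(preset)
            tight = ScenarioConfig(params=base.params, t_end=base.t_end,
                                   rtol=base.rtol / 2, atol=base.atol / 2)
            a = integrate(base).final_state.as_tuple()
            b = integrate(tight).final_state.as_tuple()
            assert a == pytest.approx(b, abs=1e-6)

    def test_trajectories_stay_in_cube_random(self, random_params_small):
        rng = np.random.default_rng(17)
        for params in random_params_small[:30]:
            for _ in range(2):
                config = ScenarioConfig(params=params,
                                        initial_state=MixedState(*rng.random(3)),
                                        t_end=30.0)
                traj = integrate(config)
                assert np.all((traj.states >= 0.0) & (traj.states <= 1.0))


class TestConvergence:
    def test_preset1_converges_to_origin(self):
        result = converged_state(integrate(scenario_config(1)), tol=1e-3)
        assert result is not None
        assert result.as_tuple() == pytest.approx((0, 0, 0), abs=1e-3)

    def test_constant_corner_trajectory_converges_to_itself(self, scenario3):
        traj = integrate(ScenarioConfig(params=scenario3,
                                        initial_state=MixedState(1, 0, 1)))
        assert converged_state(traj).as_tuple() == (1, 0, 1)

    def test_short_moving_trajectory_not_converged(self, scenario1):
        traj = integrate(ScenarioConfig(params=scenario1, t_end=0.5, n_points=2))
        assert converged_state(traj, tol=1e-3) is None

    def test_converged_endpoint_is_an_ess(self, random_params_small):
        """A settled trajectory lands (within 0.02) on an ESS corner,
        never on an unstable one; saddle landings occur only along the
        saddle's numerically absorbed stable set (every escape direction
        below the detector's rate resolution)."""
        from fraudgame.stability import jacobian_at

        tol = 1e-3
        rng = np.random.default_rng(23)
        for params in random_params_small[:25]:
            start = MixedState(*(0.05 + 0.9 * rng.random(3)))
            traj = integrate(ScenarioConfig(params=params, initial_state=start))
            endpoint = converged_state(traj, tol=tol)
            if endpoint is None:
                continue
            matches = [label for label, coords in CORNERS.items()
                       if max(abs(a - b) for a, b in
                              zip(endpoint.as_tuple(), coords)) < 0.02]
            if not matches:
                continue  # settled on a face segment, not a corner
            cls = classify(params, matches[0])
            assert cls is not StabilityClass.UNSTABLE
            if cls is StabilityClass.SADDLE:
                corner = CORNERS[matches[0]]
                diag = np.diag(jacobian_at(params, MixedState(*corner)))
                for lam, e, c in zip(diag, endpoint.as_tuple(), corner):
                    if lam > 0:
                        assert lam * abs(e - c) < 2.0 * tol


class TestCrossingTimes:
    def test_interpolated_crossing(self, scenario1):
        traj = integrate(scenario_config(1))
        t = time_to_threshold(traj, "z", 0.1, "below")
        assert t is not None and 0.0 < t < 1.0
        # z starts at 0.2 and decays monotonically here
        i = np.searchsorted(traj.times, t)
        assert traj.states[i - 1, 2] >= 0.1 >= traj.states[i, 2]

    def test_unreached_level(self, scenario3):
        traj = integrate(ScenarioConfig(params=scenario3,
                                        initial_state=MixedState(1, 0, 1)))
        assert time_to_threshold(traj, "x", 0.5, "below") is None

    def test_higher_supervision_cost_speeds_disengagement(self):
        t_cheap = time_to_threshold(
            integrate(scenario_config(1)), "z", 0.1, "below")
        t_costly = time_to_threshold(
            integrate(scenario_config(1, {"Cg": 11.0})), "z", 0.1, "below")
        assert t_costly < t_cheap

    def test_higher_hospital_fine_speeds_compliance(self):
        t_low = time_to_threshold(
            integrate(scenario_config(3, {"Ph": 4.5})), "x", 0.9, "above")
        t_high = time_to_threshold(
            integrate(scenario_config(3, {"Ph": 5.5})), "x", 0.9, "above")
        assert t_high < t_low


class TestRunScenario:
    def test_scenario1_context(self):
        result = run_scenario(1)
        assert result.converged is not None
        assert result.converged.as_tuple() == pytest.approx((0, 0, 0), abs=0.01)
        assert result.flags.A and not result.flags.B and not result.flags.C

    def test_scenario3_context(self):
        result = run_scenario(3)
        assert result.converged.as_tuple() == pytest.approx((1, 0, 1), abs=0.01)
        assert result.flags.C

    def test_override_flips_supervised_equilibrium(self):
        """Raising the supervision cost past Ag+Pg+Ph+Pt destabilizes the
        supervised-fraud corner in scenario 2."""
        result = run_scenario(2, overrides={"Cg": 9.5})
        frame = result.report.to_dataframe()
        lam1 = frame.loc[frame.point == "E4", "lambda1"].item()
        assert lam1 == pytest.approx(1.2)
        assert frame.loc[frame.point == "E4", "class"].item() != "ESS"

    def test_invalid_override_rejected(self):
        with pytest.raises(ValueError, match="Ag<Cg"):
            run_scenario(1, overrides={"Cg": 1.0})


class TestSweeps:
    def test_metric_parsing(self):
        spec = parse_metric("time-to:z<0.1")
        assert spec == MetricSpec("time_to", "z", 0.1, "below")
        assert parse_metric("final") == MetricSpec("final")
        with pytest.raises(ValueError):
            parse_metric("time-to:w<0.1")

    def test_supervision_cost_sweep_direction(self):
        result = parameter_sweep(scenario_config(1), "Cg", [9.0, 10.0, 11.0],
                                 "time-to:z<0.1")
        times = result.metric_values()
        assert all(t is not None for t in times)
        assert times[0] > times[1] > times[2]

    def test_superior_reward_sweep_direction(self):
        result = parameter_sweep(scenario_config(2), "Ag", [2.0, 3.0, 4.0],
                                 "time-to:z>0.9")
        times = result.metric_values()
        assert times[0] > times[1] > times[2]

    def test_invalid_value_flagged_but_sweep_continues(self):
        result = parameter_sweep(scenario_config(1), "Cg", [9.0, 1.0, 11.0],
                                 "time-to:z<0.1")
        assert [row.valid for row in result.rows] == [True, False, True]
        assert "Ag<Cg" in result.rows[1].note

    def test_empty_sweep(self):
        result = parameter_sweep(scenario_config(1), "Cg", [], "final")
        assert result.rows == ()


class TestSampler:
    def test_returns_strictly_valid_sets(self):
        params = sample_valid_parameters(42)
        assert validate_parameters(params, strict=True) == []

    def test_deterministic(self):
        assert sample_valid_parameters(42) == sample_valid_parameters(42)

    @pytest.mark.parametrize("condition", ["A", "B", "C"])
    def test_conditional_sampling(self, condition):
        params = sample_valid_parameters(42, condition)
        assert validate_parameters(params, strict=True) == []
        assert getattr(condition_flags(params), condition)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            sample_valid_parameters(1, "D")
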