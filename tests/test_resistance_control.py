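"""Inverse resistance solvers: zero-axial, zero-shear, torque compensation."""

import math

import numpy as np
import pytest

from jointload import (
    InfeasibleConfiguration,
    JointState,
    SolverBounds,
    TorqueProfile,
    beta_zero_axial,
    commanded_torque,
    parabolic_profile,
    plan_exercise,
    quasi_static_profile,
    rp_zero_shear_quasistatic,
    solve_configuration,
)

DEG = math.pi / 180.0
END_RANGE = 16.4


class TestBetaZeroAxial:
    def test_distal_pad_end_range(self, anat):
        assert beta_zero_axial(END_RANGE, 0.40, anat) == pytest.approx(-82.9, abs=0.1)

    def test_proximal_pad_end_range(self, anat):
        assert beta_zero_axial(END_RANGE, 0.05, anat) == pytest.approx(-45.0, abs=0.1)

    def test_limit_of_vanishing_application_distance(self, anat):
        assert beta_zero_axial(END_RANGE, 1e-9, anat) == pytest.approx(0.0, abs=1e-5)
        assert beta_zero_axial(END_RANGE, 1e-3, anat) < 0

    def test_always_in_open_negative_quadrant(self, anat):
        for flexion in np.linspace(0, 120, 25):
            for rP in (0.05, 0.1, 0.2, 0.4):
                beta = beta_zero_axial(float(flexion), rP, anat)
                assert -90.0 < beta < 0.0

    def test_magnitude_strictly_increasing_in_rp(self, anat):
        rPs = np.linspace(0.01, 0.5, 40)
        betas = [abs(beta_zero_axial(60.0, float(r), anat)) for r in rPs]
        assert all(a < b for a, b in zip(betas, betas[1:]))


class TestRpZeroShear:
    def test_end_range_solution_feasible(self, anat):
        rP, flag = rp_zero_shear_quasistatic(END_RANGE, anat)
        assert rP == pytest.approx(0.1756, abs=1e-4)
        assert flag == "feasible"

    def test_deep_flexion_always_pcl(self, anat):
        rP, flag = rp_zero_shear_quasistatic(120.0, anat)
        assert flag == "always_pcl"
        assert rP == math.inf

    def test_feasibility_boundary_near_50_degrees(self, anat):
        flags = {
            float(f): rp_zero_shear_quasistatic(float(f), anat)[1]
            for f in np.linspace(0, 120, 121)
        }
        feasible = [f for f, fl in flags.items() if fl == "feasible"]
        assert 45.0 < max(feasible) < 52.0
        assert min(feasible) == 0.0


class TestCommandedTorque:
    def test_quasi_static_passthrough(self):
        tau, ok = commanded_torque(30.0, 0.0, 0.457)
        assert tau == 30.0 and ok

    def test_extreme_acceleration_turns_assistive(self):
        # 30 N*m - 0.457 kg*m^2 * 4000 deg/s^2 -> about -1.9 N*m
        tau, ok = commanded_torque(30.0, 4000.0, 0.457)
        assert tau == pytest.approx(-1.9, abs=0.05)
        assert not ok

    def test_deceleration_raises_commanded_torque(self):
        tau, ok = commanded_torque(30.0, -1000.0, 0.457)
        assert tau > 30.0 and ok


class TestSolveConfiguration:
    def test_zero_shear_reduces_to_pad_placement_rule(self, seg, anat):
        result = solve_configuration(
            JointState(END_RANGE), 30.0, seg, anat, shear_target_n=0.0
        )
        rP_star, _ = rp_zero_shear_quasistatic(END_RANGE, anat)
        assert result.config.rP_m == pytest.approx(rP_star)
        assert result.config.beta_deg == 0.0
        assert result.reaction.shear_n == pytest.approx(0.0, abs=1e-9)

    def test_zero_axial_reduces_to_direction_rule(self, seg, anat):
        result = solve_configuration(
            JointState(30.0), 30.0, seg, anat, axial_target_n=0.0, rP_default_m=0.30
        )
        assert result.config.beta_deg == pytest.approx(
            beta_zero_axial(30.0, 0.30, anat)
        )
        assert result.reaction.axial_n == pytest.approx(0.0, abs=1e-9)

    def test_zero_axial_direction_independent_of_torque_level(self, seg, anat):
        betas = [
            solve_configuration(
                JointState(45.0), tau, seg, anat, axial_target_n=0.0,
                rP_default_m=0.25,
            ).config.beta_deg
            for tau in (10.0, 40.0, 80.0)
        ]
        assert betas[0] == pytest.approx(betas[1]) == pytest.approx(betas[2])

    def test_torque_constraint_always_preserved(self, seg, anat):
        result = solve_configuration(
            JointState(40.0, 100.0, 500.0), 25.0, seg, anat,
            shear_target_n=0.0, axial_target_n=0.0, tau_phi_nm=-2.0,
        )
        cfg = result.config
        assert cfg.torque_nm == pytest.approx(25.0, rel=1e-12)

    def test_plug_back_on_seeded_random_dynamic_states(self, seg, anat):
        """Feasible solves must reproduce their targets through the forward
        model and preserve the commanded torque, to solver precision."""
        rng = np.random.default_rng(20260226)
        bounds = SolverBounds(rP_min_m=0.01, rP_max_m=1.0, beta_limit_deg=89.9)
        checked = 0
        for _ in range(500):
            state = JointState(
                rng.uniform(0, 120), rng.uniform(-400, 400), rng.uniform(-3000, 3000)
            )
            tau_cmd = rng.uniform(5.0, 60.0)
            shear_t = rng.uniform(-150.0, 150.0)
            axial_t = rng.uniform(-300.0, 300.0)
            result = solve_configuration(
                state, tau_cmd, seg, anat,
                shear_target_n=shear_t, axial_target_n=axial_t,
                tau_phi_nm=rng.uniform(-12.0, 0.0), bounds=bounds, strict=False,
            )
            if not result.feasible:
                continue
            checked += 1
            assert abs(result.reaction.shear_n - shear_t) < 1e-8
            assert abs(result.reaction.axial_n - axial_t) < 1e-8
            assert abs(result.config.torque_nm - tau_cmd) < 1e-8
        assert checked > 100  # the random box must actually exercise the solver

    def test_assistive_demand_raises_in_strict_mode(self, seg, anat):
        with pytest.raises(InfeasibleConfiguration, match="assistive"):
            solve_configuration(JointState(60.0), -5.0, seg, anat)

    def test_out_of_bounds_rp_flagged_when_not_strict(self, seg, anat):
        # deep flexion: zero shear unreachable (always-PCL regime)
        result = solve_configuration(
            JointState(110.0), 30.0, seg, anat, shear_target_n=0.0, strict=False
        )
        assert not result.feasible
        assert "rP" in result.violation

    def test_bound_violation_carries_constraint_name(self, seg, anat):
        bounds = SolverBounds(R_max_n=50.0)
        with pytest.raises(InfeasibleConfiguration, match="R_max"):
            solve_configuration(
                JointState(60.0), 40.0, seg, anat, rP_default_m=0.40, bounds=bounds
            )


class TestPlanExercise:
    def test_quasi_static_zero_shear_feasibility_matches_pointwise_rule(
        self, seg, anat
    ):
        profile = quasi_static_profile(n_samples=61)
        plan = plan_exercise(
            profile, TorqueProfile.constant(30.0), "zero_shear", seg, anat
        )
        for _, row in plan.samples.iterrows():
            _, flag = rp_zero_shear_quasistatic(row.flexion_deg, anat)
            assert row.feasible == (flag == "feasible")
            if row.feasible:
                assert abs(row.shear_N) < 1e-9

    def test_plain_mode_uses_distal_pad_perpendicular_pull(self, seg, anat):
        profile = quasi_static_profile(n_samples=13)
        plan = plan_exercise(
            profile, TorqueProfile.constant(30.0), "plain", seg, anat
        )
        assert (plan.samples.beta_deg == 0.0).all()
        assert np.allclose(plan.samples.rP_m, 0.40)
        assert np.allclose(plan.samples.R_N, 30.0 / 0.40)

    def test_dynamic_zero_shear_nulls_shear_at_feasible_samples(self, seg, anat):
        with pytest.warns(UserWarning, match="excursion"):
            profile = parabolic_profile(500.0, 0.5, n_samples=101)
        plan = plan_exercise(
            profile, TorqueProfile.constant(30.0), "zero_shear", seg, anat
        )
        feasible = plan.samples[plan.samples.feasible]
        assert len(feasible) > 0
        assert np.abs(feasible.shear_N).max() < 1e-8
        # torque constraint holds wherever solved
        assert np.allclose(
            feasible.R_N * feasible.rP_m * np.cos(feasible.beta_deg * DEG),
            feasible.tau_cmd_Nm,
            rtol=1e-8,
        )

    def test_zero_shear_never_raises_compression_over_plain(self, seg, anat):
        """At equal commanded torque the zero-shear pad placement must not
        increase axial compression relative to the conventional distal pad."""
        profile = quasi_static_profile(n_samples=61)
        tau = TorqueProfile.constant(30.0)
        zs = plan_exercise(profile, tau, "zero_shear", seg, anat).samples
        plain = plan_exercise(profile, tau, "plain", seg, anat).samples
        mask = zs.feasible.to_numpy()
        assert (
            zs.axial_N.to_numpy()[mask] <= plain.axial_N.to_numpy()[mask] + 1e-9
        ).all()

    def test_zero_both_nulls_both_components(self, seg, anat):
        profile = quasi_static_profile(0.0, 45.0, n_samples=31)
        bounds = SolverBounds(rP_min_m=0.01, rP_max_m=1.0, beta_limit_deg=89.9)
        plan = plan_exercise(
            profile, TorqueProfile.constant(20.0), "zero_both", seg, anat,
            bounds=bounds,
        )
        feasible = plan.samples[plan.samples.feasible]
        assert len(feasible) > 10
        assert np.abs(feasible.shear_N).max() < 1e-8
        assert np.abs(feasible.axial_N).max() < 1e-8

    def test_unknown_mode_rejected(self, seg, anat):
        with pytest.raises(ValueError, match="mode"):
            plan_exercise(
                quasi_static_profile(n_samples=5), TorqueProfile.constant(30.0),
                "minimise", seg, anat,
            )


class TestTorqueProfile:
    def test_tabulated_profile_interpolates(self):
        prof = TorqueProfile.from_table([0.0, 60.0, 120.0], [20.0, 40.0, 30.0])
        assert prof.tau_at(30.0) == pytest.approx(30.0)

    def test_nonpositive_profile_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TorqueProfile.constant(0.0)
        with pytest.raises(ValueError, match="positive"):
            TorqueProfile.from_table([0.0, 120.0], [10.0, -1.0])

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError, match="rP_min"):
            SolverBounds(rP_min_m=0.5, rP_max_m=0.4)
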