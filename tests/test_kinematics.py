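"""Inverse kinematics (against rigid-registration and grid oracles),
filtering, and differentiation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mocapuq.errors import DomainError, UnderdeterminedError
from mocapuq.kinematics import (
    MarkerTrajectories,
    differentiate,
    gauss_newton_pose,
    lowpass_filter,
    solve_ik,
    solve_ik_frame,
)
from mocapuq.model import compute_state, forward_kinematics

from conftest import make_pendulum


def _objective(model, q, observed, weights):
    pos = forward_kinematics(model, q)
    return sum(
        weights.get(n, 1.0) * np.sum((pos[n] - np.asarray(o)) ** 2)
        for n, o in observed.items()
        if n in pos and weights.get(n, 1.0) > 0
    )


class TestSolveIkFrame:
    def test_zero_residual_fixed_point(self, gait_model):
        rng = np.random.default_rng(0)
        q_true = gait_model.neutral_pose() + rng.normal(0, 0.15, gait_model.n_coordinates)
        observed = forward_kinematics(gait_model, q_true)
        q, errors = solve_ik_frame(gait_model, observed, initial_guess=q_true)
        assert max(errors.values()) < 1e-8
        assert np.allclose(q, q_true, atol=1e-7)

    def test_rigid_transform_recovered_vs_kabsch(self, free_body):
        """A free segment posed against rigidly transformed markers must
        reproduce the transform found by closed-form rigid registration."""
        rng = np.random.default_rng(4)
        R_true = Rotation.from_rotvec(rng.normal(0, 0.4, 3))
        t_true = rng.normal(0, 0.3, 3)
        local = np.array([m.local_position for m in free_body.markers])
        target = R_true.apply(local) + t_true
        observed = dict(zip(free_body.marker_names, target))
        q, errors = solve_ik_frame(free_body, observed)
        assert max(errors.values()) < 1e-6
        # oracle: Kabsch on the same point sets
        R_est, _ = Rotation.align_vectors(
            target - target.mean(axis=0), local - local.mean(axis=0)
        )
        st = compute_state(free_body, q)
        assert np.allclose(st.R[0], R_est.as_matrix(), atol=1e-6)
        assert np.allclose(st.p[0], target.mean(axis=0) - R_est.apply(local.mean(axis=0)),
                           atol=1e-6)

    def test_single_offset_marker_vs_grid_oracle(self):
        """With one marker displaced 1 cm, the 1-dof optimum must match a
        brute-force grid refinement of the objective."""
        model = make_pendulum()
        q_true = np.array([0.3])
        observed = forward_kinematics(model, q_true)
        observed["mid"] = observed["mid"] + np.array([0.0, 0.01, 0.0])
        weights = {n: 1.0 for n in model.marker_names}
        q, _ = solve_ik_frame(model, observed, weights, q_true)
        grid = np.arange(q_true[0] - 0.05, q_true[0] + 0.05, 1e-4)
        vals = [_objective(model, [g], observed, weights) for g in grid]
        q_grid = grid[int(np.argmin(vals))]
        assert abs(q[0] - q_grid) < 1e-4
        assert _objective(model, q, observed, weights) <= min(vals) + 1e-15

    def test_underdetermined_too_few_markers(self, free_body):
        with pytest.raises(UnderdeterminedError):
            solve_ik_frame(free_body, {"m0": (0.1, 0, 0), "m1": (0, 0.1, 0)})

    def test_underdetermined_collinear(self, free_body):
        obs = {"m0": (0, 0, 0), "m1": (0.1, 0, 0), "m2": (0.2, 0, 0)}
        with pytest.raises(UnderdeterminedError, match="collinear"):
            solve_ik_frame(free_body, obs)

    def test_zero_weight_cannot_worsen_objective(self, gait_model):
        rng = np.random.default_rng(7)
        q_true = gait_model.neutral_pose() + rng.normal(0, 0.1, gait_model.n_coordinates)
        observed = {
            n: p + rng.normal(0, 0.005, 3)
            for n, p in forward_kinematics(gait_model, q_true).items()
        }
        w_all = {n: 1.0 for n in gait_model.marker_names}
        q_all, _ = solve_ik_frame(gait_model, observed, w_all, q_true)
        w_drop = dict(w_all, RTOE=0.0)
        q_drop, _ = solve_ik_frame(gait_model, observed, w_drop, q_true)
        # objective without RTOE can only improve once RTOE stops pulling
        assert (
            _objective(gait_model, q_drop, observed, w_drop)
            <= _objective(gait_model, q_all, observed, w_drop) + 1e-12
        )

    def test_gauss_newton_matches_reference_solver(self, gait_model):
        rng = np.random.default_rng(11)
        q_true = gait_model.neutral_pose() + rng.normal(0, 0.1, gait_model.n_coordinates)
        observed = forward_kinematics(gait_model, q_true)
        q_ref, _ = solve_ik_frame(gait_model, observed, initial_guess=None)
        q_gn = gauss_newton_pose(gait_model, observed)
        assert np.allclose(q_gn, q_ref, atol=1e-8)


class TestSolveIkTrajectory:
    def test_noise_free_gait_recovery(self, trial):
        sol = solve_ik(trial.model, trial.trajectories)
        assert np.abs(sol.coordinates - trial.true_q).max() < 1e-6
        assert np.nanmax(sol.rmse_per_frame) < 1e-8

    def test_constant_pose_identical_frames(self, gait_model):
        q = gait_model.neutral_pose()
        pos = compute_state(gait_model, q).marker_positions
        traj = MarkerTrajectories(
            times=np.arange(10) * 0.01, rate=100.0,
            names=gait_model.marker_names,
            positions=np.repeat(pos[None], 10, axis=0),
        )
        sol = solve_ik(gait_model, traj)
        assert np.allclose(sol.coordinates, sol.coordinates[0], atol=1e-10)

    def test_missing_marker_excluded_from_frame(self, trial):
        pos = trial.trajectories.positions.copy()
        names = trial.trajectories.names
        k = names.index("RTOE") if isinstance(names, list) else list(names).index("RTOE")
        pos[5, k] = np.nan  # RTOE drops out at frame 5
        traj = MarkerTrajectories(
            times=trial.times, rate=trial.params.rate, names=names, positions=pos
        )
        sol = solve_ik(trial.model, traj)
        assert np.isnan(sol.per_marker_error["RTOE"][5])
        # equals a solve where that observation never existed
        obs = trial.trajectories.frame(5)
        del obs["RTOE"]
        q_ref, _ = solve_ik_frame(trial.model, obs, None, sol.coordinates[4])
        assert np.allclose(sol.coordinates[5], q_ref, atol=1e-9)

    def test_rmse_consistent_with_marker_errors(self, trial):
        sol = solve_ik(trial.model, trial.trajectories)
        errs = np.array([sol.per_marker_error[n] for n in trial.trajectories.names])
        expect = np.sqrt(np.nanmean(errs**2, axis=0))
        assert np.allclose(sol.rmse_per_frame, expect, atol=1e-12)

    def test_batch_invariance_of_warm_start(self, trial):
        """Solving all frames equals solving two halves with the carried
        guess."""
        full = solve_ik(trial.model, trial.trajectories)
        T = trial.times.shape[0]
        half = T // 2

        def sub(sl, guess):
            traj = MarkerTrajectories(
                times=trial.times[sl], rate=trial.params.rate,
                names=trial.trajectories.names,
                positions=trial.trajectories.positions[sl],
            )
            return solve_ik(trial.model, traj, initial_guess=guess)

        first = sub(slice(0, half), None)
        second = sub(slice(half, T), first.coordinates[-1])
        stitched = np.vstack([first.coordinates, second.coordinates])
        assert np.array_equal(stitched, full.coordinates)


class TestFilter:
    def test_constant_signal_unchanged(self):
        x = np.full(200, 3.7)
        assert np.allclose(lowpass_filter(x, 100.0, 6.0), x, atol=1e-10)

    def test_passband_amplitude_preserved(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_filter(x, 100.0, 6.0)
        mid = slice(200, 800)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 30.0 * t)
        y = lowpass_filter(x, 100.0, 6.0)
        assert np.abs(y[200:800]).max() < 10 ** (-20 / 20)  # > 20 dB down

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(DomainError):
            lowpass_filter(np.zeros(100), 100.0, 60.0)


class TestDifferentiate:
    def test_linear_ramp(self):
        t = np.arange(0, 1, 0.01)
        d = differentiate(2.0 * t, t)
        assert np.allclose(d.velocities, 2.0, atol=1e-12)
        assert np.allclose(d.accelerations[2:-2], 0.0, atol=1e-10)

    def test_quadratic_acceleration(self):
        t = np.arange(0, 1, 0.01)
        d = differentiate(t**2, t)
        assert np.allclose(d.accelerations[2:-2], 2.0, atol=1e-9)

    def test_sinusoid_second_order_convergence(self):
        errs = []
        for dt in (0.01, 0.005):
            t = np.arange(0, 1 + dt / 2, dt)
            d = differentiate(np.sin(2 * np.pi * t), t)
            ref = 2 * np.pi * np.cos(2 * np.pi * t)
            errs.append(np.abs(d.velocities[1:-1] - ref[1:-1]).max())
        assert errs[1] < errs[0] / 3.0  # ~4x for O(dt^2)

    def test_too_few_frames_rejected(self):
        with pytest.raises(DomainError):
            differentiate(np.array([0.0, 1.0]), np.array([0.0, 0.1]))

    def test_filter_then_differentiate_matches_analytic(self):
        """Band-limited signal (well below cutoff/2): filtering then
        differentiating reproduces the analytic derivative within 2%."""
        t = np.arange(0, 4, 0.01)
        x = np.sin(2 * np.pi * 1.5 * t)
        y = lowpass_filter(x, 100.0, 6.0)
        d = differentiate(y, t)
        ref = 2 * np.pi * 1.5 * np.cos(2 * np.pi * 1.5 * t)
        mid = slice(50, -50)
        assert np.abs(d.velocities[mid] - ref[mid]).max() < 0.02 * np.abs(ref).max()
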