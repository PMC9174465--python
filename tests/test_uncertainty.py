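"""Ensemble samplers, marker-error metrics, peak extraction, and crouch
classification."""

import numpy as np
import pytest

from mocapuq.errors import DomainError, RejectionCapError
from mocapuq.events import GaitEvents
from mocapuq.kinematics import solve_ik_frame
from mocapuq.model import ScaleFactorSet, compute_state, forward_kinematics
from mocapuq.uncertainty import (
    METRIC_NAMES,
    DEFAULT_PEAK_CONFIG,
    PeakMetrics,
    UncertaintyConfig,
    build_ensemble,
    classification_range,
    classify_crouch,
    extract_peaks,
    marker_error_metrics,
    metric_ranges,
    perturb_markers,
    run_pipeline,
    run_single_model,
    sample_in_ball,
    sample_scaled_model,
)


class TestRegistrationSampler:
    def test_zero_radius_identity(self, gait_model):
        rng = np.random.default_rng(0)
        out = perturb_markers(gait_model, 0.0, rng)
        assert out.to_dict() == gait_model.to_dict()

    def test_offsets_within_ball(self, gait_model):
        rng = np.random.default_rng(1)
        e = 0.02
        for _ in range(50):
            out = perturb_markers(gait_model, e, rng)
            for m0, m1 in zip(gait_model.markers, out.markers):
                off = np.asarray(m1.local_position) - np.asarray(m0.local_position)
                assert np.linalg.norm(off) <= e

    def test_mean_radius_three_quarters(self):
        """E||X|| = 3e/4 for the uniform ball (independent MC identity)."""
        rng = np.random.default_rng(2)
        r = np.array(
            [np.linalg.norm(sample_in_ball(1.0, rng)) for _ in range(20000)]
        )
        assert r.mean() == pytest.approx(0.75, abs=0.005)

    def test_per_marker_radius_map(self, gait_model):
        rng = np.random.default_rng(3)
        out = perturb_markers(
            gait_model, 0.02, rng, per_marker_e={"RASI": 0.0}
        )
        assert out.marker("RASI").local_position == \
            gait_model.marker("RASI").local_position

    def test_only_markers_touched(self, gait_model):
        rng = np.random.default_rng(4)
        out = perturb_markers(gait_model, 0.01, rng)
        assert tuple(out.segments) == tuple(gait_model.segments)

    def test_deterministic_given_rng(self, gait_model):
        a = perturb_markers(gait_model, 0.01, np.random.default_rng(5))
        b = perturb_markers(gait_model, 0.01, np.random.default_rng(5))
        assert a.to_dict() == b.to_dict()

    def test_negative_radius_rejected(self, gait_model):
        with pytest.raises(DomainError):
            perturb_markers(gait_model, -0.1, np.random.default_rng(0))


class TestScaleSampler:
    def test_near_unit_interval_accepted(self, gait_model):
        rng = np.random.default_rng(0)
        model, factors = sample_scaled_model(
            gait_model, 0.005, (0.999, 1.001), gait_model.neutral_pose(), rng
        )
        for v in factors.factors.values():
            assert 0.999 <= v[0] <= 1.001

    def test_gross_scaling_rejected(self, gait_model):
        """Near +10% thigh scaling moves distal markers by centimeters; no
        draw can pass at e = 5 mm."""
        rng = np.random.default_rng(1)
        with pytest.raises(RejectionCapError, match="increase e"):
            sample_scaled_model(
                gait_model, 0.005, (1.099, 1.10), gait_model.neutral_pose(),
                rng, rejection_cap=300,
            )

    def test_accepted_model_passes_exact_recheck(self, gait_model):
        """Independent re-check with the reference IK solver: all marker
        distances at the calibration pose stay within e."""
        e = 0.01
        q0 = gait_model.neutral_pose()
        ref = compute_state(gait_model, q0).marker_positions
        obs = dict(zip(gait_model.marker_names, ref))
        for seed in range(3):
            rng = np.random.default_rng(seed)
            model, _ = sample_scaled_model(gait_model, e, (0.9, 1.1), q0, rng)
            q, _ = solve_ik_frame(model, obs, None, q0)
            pos = compute_state(model, q).marker_positions
            assert np.linalg.norm(pos - ref, axis=1).max() <= e

    def test_seeded_run_reproducible(self, gait_model):
        q0 = gait_model.neutral_pose()
        _, fa = sample_scaled_model(
            gait_model, 0.01, (0.9, 1.1), q0, np.random.default_rng(42)
        )
        _, fb = sample_scaled_model(
            gait_model, 0.01, (0.9, 1.1), q0, np.random.default_rng(42)
        )
        assert fa.factors == fb.factors


class TestBuildEnsemble:
    def test_levels_nested_by_augmentation(self, gait_model):
        cfg = UncertaintyConfig(
            strategy="marker_registration", levels_e=(0.005, 0.01), N=2, seed=9
        )
        ens = build_ensemble(gait_model, cfg)
        lvl1 = ens.analysis_members(0)
        lvl2 = ens.analysis_members(1)
        assert len(lvl1) == 2 and len(lvl2) == 4
        assert set(m.key for m in lvl1) <= set(m.key for m in lvl2)

    def test_no_augment_gives_fresh_sets(self, gait_model):
        cfg = UncertaintyConfig(
            strategy="marker_registration", levels_e=(0.005, 0.01), N=2,
            seed=9, augment_previous=False,
        )
        ens = build_ensemble(gait_model, cfg)
        assert len(ens.analysis_members(1)) == 2

    def test_zero_models_rejected(self):
        with pytest.raises(DomainError):
            UncertaintyConfig(strategy="marker_registration", N=0)

    def test_bad_strategy_rejected(self):
        with pytest.raises(DomainError):
            UncertaintyConfig(strategy="voodoo")

    def test_same_seed_bit_identical(self, gait_model):
        cfg = UncertaintyConfig(
            strategy="marker_registration", levels_e=(0.01,), N=3, seed=123
        )
        a = build_ensemble(gait_model, cfg)
        b = build_ensemble(gait_model, cfg)
        for ma, mb in zip(a.all_members, b.all_members):
            assert ma.model.to_dict() == mb.model.to_dict()


class TestMarkerErrorMetrics:
    def test_identical_models_zero(self, trial):
        from mocapuq.kinematics import marker_position_trajectory, solve_ik

        sol = solve_ik(trial.model, trial.trajectories)
        ref = marker_position_trajectory(trial.model, sol.coordinates)
        rmse, mx = marker_error_metrics(
            [trial.model], [sol], ref, trial.model.marker_names
        )
        assert rmse == 0.0 and mx == 0.0

    def test_constant_error_gives_that_constant(self, trial):
        from mocapuq.kinematics import marker_position_trajectory, solve_ik

        sol = solve_ik(trial.model, trial.trajectories)
        ref = marker_position_trajectory(trial.model, sol.coordinates)
        d = 0.007
        shifted = ref + np.array([0.0, d, 0.0])  # every marker off by d
        rmse, mx = marker_error_metrics(
            [trial.model], [sol], shifted, trial.model.marker_names
        )
        assert rmse == pytest.approx(d, rel=1e-12)
        assert mx == pytest.approx(d, rel=1e-12)

    def test_matches_naive_double_loop(self, trial, gait_model):
        from mocapuq.kinematics import marker_position_trajectory, solve_ik

        rng = np.random.default_rng(0)
        models = [perturb_markers(gait_model, 0.01, rng) for _ in range(3)]
        sols = [solve_ik(m, trial.trajectories) for m in models]
        base = solve_ik(gait_model, trial.trajectories)
        ref = marker_position_trajectory(gait_model, base.coordinates)
        rmse, mx = marker_error_metrics(models, sols, ref, gait_model.marker_names)
        # naive oracle
        per_model = []
        worst = 0.0
        for m, s in zip(models, sols):
            frames = []
            for t in range(len(trial.times)):
                pos = forward_kinematics(m, s.coordinates[t])
                errs = [
                    np.linalg.norm(pos[n] - ref[t, i])
                    for i, n in enumerate(gait_model.marker_names)
                ]
                worst = max(worst, max(errs))
                frames.append(np.sqrt(np.mean(np.square(errs))))
            per_model.append(np.mean(frames))
        assert rmse == pytest.approx(max(per_model), abs=1e-12)
        assert mx == pytest.approx(worst, abs=1e-12)

    def test_empty_ensemble_rejected(self, trial):
        with pytest.raises(DomainError):
            marker_error_metrics([], [], np.zeros((1, 1, 3)), ["a"])


def _events(T, stance_to, push_from):
    stance = np.zeros(T, bool)
    stance[:stance_to] = True
    push = np.zeros(T, bool)
    push[push_from:stance_to] = True
    return GaitEvents(times=np.arange(T) / 100.0, stance=stance, pushoff=push)


class TestExtractPeaks:
    names = ("hip_flexion_r", "knee_flexion_r", "ankle_angle_r")

    def _cfg(self):
        from mocapuq.uncertainty import PeakConfig

        return PeakConfig(
            hip_flexion="hip_flexion_r",
            knee_flexion="knee_flexion_r",
            ankle_dorsiflexion="ankle_angle_r",
        )

    def test_constant_zero_gives_zero_peaks(self):
        T = 50
        z = np.zeros((T, 3))
        pk = extract_peaks(z, z, z, _events(T, 30, 18), self.names, self._cfg())
        assert all(v == 0.0 for v in pk.as_dict().values())

    def test_injected_maximum_recovered(self):
        T = 50
        ang = np.zeros((T, 3))
        mom = np.zeros((T, 3))
        pwr = np.zeros((T, 3))
        ang[40, 0] = np.deg2rad(-17.0)  # hip extension peak (swing ok)
        ang[10, 1] = np.deg2rad(-3.0)  # knee min during stance
        mom[25, 2] = -42.0  # plantarflexion moment
        pwr[25, 2] = 99.0  # within push-off window
        ev = _events(T, 30, 18)
        pk = extract_peaks(ang, mom, pwr, ev, self.names, self._cfg())
        assert pk.peak_hip_extension_angle == pytest.approx(17.0)
        assert pk.min_knee_flexion_angle_stance == pytest.approx(-3.0)
        assert pk.peak_ankle_plantarflexion_moment == pytest.approx(42.0)
        assert pk.peak_ankle_power_pushoff == pytest.approx(99.0)

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(8)
        T = 80
        ang = rng.normal(0, 0.3, (T, 3))
        mom = rng.normal(0, 50, (T, 3))
        pwr = rng.normal(0, 80, (T, 3))
        ev = _events(T, 48, 29)
        pk = extract_peaks(ang, mom, pwr, ev, self.names, self._cfg())
        st = ev.stance
        po = ev.pushoff
        assert pk.peak_hip_extension_angle == pytest.approx(
            np.rad2deg(-ang[:, 0]).max()
        )
        assert pk.min_knee_flexion_angle_stance == pytest.approx(
            np.rad2deg(ang[st, 1]).min()
        )
        assert pk.peak_ankle_plantarflexion_angle == pytest.approx(
            np.rad2deg(-ang[:, 2]).max()
        )
        assert pk.peak_hip_flexion_moment == pytest.approx(mom[:, 0].max())
        assert pk.peak_knee_flexion_moment_stance == pytest.approx(mom[st, 1].max())
        assert pk.peak_ankle_plantarflexion_moment == pytest.approx((-mom[:, 2]).max())
        assert pk.peak_hip_power_pushoff == pytest.approx(pwr[po, 0].max())
        assert pk.min_knee_power_stance == pytest.approx(pwr[st, 1].min())
        assert pk.peak_ankle_power_pushoff == pytest.approx(pwr[po, 2].max())

    def test_empty_window_names_metric(self):
        T = 10
        z = np.zeros((T, 3))
        ev = GaitEvents(
            times=np.arange(T) / 100.0,
            stance=np.zeros(T, bool),
            pushoff=np.zeros(T, bool),
        )
        with pytest.raises(DomainError, match="stance"):
            extract_peaks(z, z, z, ev, self.names, self._cfg())


def _peaks(**over):
    base = {k: 0.0 for k in METRIC_NAMES}
    base.update(over)
    return PeakMetrics(**base)


class TestMetricRanges:
    def test_single_model_degenerate(self):
        r = metric_ranges([_peaks(peak_hip_flexion_moment=42.0)])
        assert r["peak_hip_flexion_moment"] == (42.0, 42.0)

    def test_two_models(self):
        r = metric_ranges(
            [_peaks(peak_hip_flexion_moment=10.0), _peaks(peak_hip_flexion_moment=20.0)]
        )
        assert r["peak_hip_flexion_moment"] == (10.0, 20.0)

    def test_nested_sets_weakly_widen(self):
        rng = np.random.default_rng(0)
        pool = [_peaks(min_knee_power_stance=v) for v in rng.normal(0, 50, 30)]
        prev = None
        for n in (5, 15, 30):
            r = metric_ranges(pool[:n])
            if prev is not None:
                for k in METRIC_NAMES:
                    assert r[k][0] <= prev[k][0]
                    assert r[k][1] >= prev[k][1]
            prev = r


class TestCrouchClassification:
    @pytest.mark.parametrize(
        "angle,category",
        [
            (10.0, "typically developing"),
            (14.99, "typically developing"),
            (15.0, "mild crouch"),
            (29.99, "mild crouch"),
            (30.0, "moderate crouch"),
            (40.0, "moderate crouch"),
            (49.99, "moderate crouch"),
            (50.0, "severe crouch"),
            (50.01, "severe crouch"),
            (55.0, "severe crouch"),
            (-5.0, "typically developing"),
        ],
    )
    def test_boundary_mapping(self, angle, category):
        assert classify_crouch(angle) == category

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            classify_crouch(float("nan"))

    def test_unambiguous_range(self):
        r = classification_range([20.0, 22.0, 25.0])
        assert r.categories == ("mild crouch",)
        assert not r.ambiguous

    def test_boundary_straddling_flags_ambiguity(self):
        r = classification_range([12.0, 18.0])
        assert r.categories == ("typically developing", "mild crouch")
        assert r.ambiguous

    def test_degenerate_boundary_value(self):
        r = classification_range([30.0])
        assert r.categories == ("moderate crouch",)
        assert not r.ambiguous


class TestRunPipeline:
    def test_identity_ensemble_matches_baseline(self, trial):
        baseline = run_single_model(
            trial.model, trial.trajectories, trial.loads, trial.events
        )
        results, failures = run_pipeline(
            [trial.model], trial.trajectories, trial.loads, trial.events
        )
        assert not failures
        out = results[0]
        assert np.array_equal(out.ik.coordinates, baseline.ik.coordinates)
        assert np.array_equal(out.moments.moments, baseline.moments.moments)
        assert np.array_equal(out.powers.powers, baseline.powers.powers)
        assert out.peaks == baseline.peaks

    def test_failures_recorded_run_continues(self, trial, gait_model):
        from mocapuq.model import LinkSegmentModel

        broken = LinkSegmentModel(
            name="broken", segments=gait_model.segments, markers=()
        )
        results, failures = run_pipeline(
            [broken, gait_model], trial.trajectories, trial.loads, trial.events
        )
        assert len(results) == 1 and 1 in results
        assert len(failures) == 1 and failures[0].index == 0
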