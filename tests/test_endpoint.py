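"""Endpoint-marker parameters: MT, CurvI, Vmax, T%Vmax, NVP, LDJ."""

import numpy as np
import pytest

from reachkin import endpoint as ep
from reachkin.errors import InsufficientDataError, InvalidArgumentError, NoMovementError
from reachkin.extract import extract_profile
from reachkin.minjerk import compose_submovements, min_jerk_profile, staircase_schedule
from reachkin.preprocess import ReachSegment, speed_profile
from reachkin.simulate import SimConfig, synth_reach_trial
from reachkin.stats import spearman

MINJERK_LDJ = -np.log(204.8)  # = -ln(720 / 1.875^2), the smoothness ceiling


class TestMovementTime:
    @pytest.mark.parametrize(
        "onset,end,fs,expected", [(0, 120, 120.0, 1.0), (12, 300, 120.0, 2.4)]
    )
    def test_arithmetic(self, onset, end, fs, expected):
        seg = ReachSegment(onset, end, "full_cycle")
        assert ep.movement_time(seg, fs) == pytest.approx(expected)

    def test_simulated_trial_matches_truth(self):
        cfg = SimConfig(n_submovements=2, marker_noise_sd=0.0, seed=5)
        rec, truth = synth_reach_trial(cfg, target_index=7)
        prof, _ = extract_profile(rec)
        # discrete frames plus 6 Hz pre-filtering widen the detected
        # window by a few frame periods relative to the continuous truth
        assert prof.MT == pytest.approx(truth.true_MT, abs=4 / cfg.sample_rate)


class TestTrajectoryDirectness:
    def test_straight_segment_is_one(self):
        path = np.linspace(0, 1, 100)[:, None] * np.array([3.0, 4.0, 0.0])
        assert ep.trajectory_directness(path) == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_is_half_pi(self):
        theta = np.linspace(0, np.pi, 500)
        path = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        assert ep.trajectory_directness(path) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_full_cycle_averages_half_cycles(self):
        theta = np.linspace(0, np.pi, 300)
        arc = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        out_and_back = np.vstack([arc, arc[::-1][1:]])
        v = ep.trajectory_directness(out_and_back, phase="full_cycle")
        assert v == pytest.approx(np.pi / 2, rel=1e-3)

    def test_coincident_endpoints_rejected_outbound(self):
        loop = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(InvalidArgumentError):
            ep.trajectory_directness(loop, phase="outbound")

    def test_simulated_curved_reach_matches_generative_path(self):
        cfg = SimConfig(path_curvature_gain=0.15, marker_noise_sd=0.0)
        rec, truth = synth_reach_trial(cfg, target_index=2)
        prof, _ = extract_profile(rec)
        assert prof.CurvI == pytest.approx(truth.true_curvature_index, rel=0.005)


class TestPeakVelocity:
    def test_minjerk_peak_and_timing(self, minjerk_reach):
        _, _, speed = minjerk_reach
        vmax, _ = ep.peak_velocity(speed)
        assert vmax == pytest.approx(56.25, rel=0.005)
        assert ep.time_to_peak_pct(speed) == pytest.approx(50.0, abs=0.5)

    def test_tie_broken_to_earliest_frame(self):
        speed = np.array([0.0, 2.0, 1.0, 2.0, 0.0])
        _, idx = ep.peak_velocity(speed)
        assert idx == 1

    def test_two_submovement_peak_in_first_window(self):
        schedule = [(0.0, 0.7, 0.45), (0.55, 0.3, 0.45)]
        t, pos = compose_submovements(schedule, 30.0, 2.0, 500.0)
        speed = np.abs(np.gradient(pos, t))
        _, idx = ep.peak_velocity(speed)
        assert t[idx] < 0.45 * 2.0


class TestCountVelocityPeaks:
    def test_minjerk_single_peak(self, minjerk_reach):
        _, _, speed = minjerk_reach
        assert ep.count_velocity_peaks(speed, 120.0) == 1

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_simulated_counts_match_ground_truth(self, k):
        cfg = SimConfig(n_submovements=k, marker_noise_sd=0.0, seed=k)
        rec, truth = synth_reach_trial(cfg, target_index=6)
        prof, _ = extract_profile(rec)
        assert prof.NVP == truth.true_n_velocity_peaks == k + 1

    def test_flat_speed_rejected(self):
        with pytest.raises(NoMovementError):
            ep.count_velocity_peaks(np.zeros(50), 120.0)


class TestLogDimensionlessJerk:
    def test_minjerk_closed_form(self):
        _, _, speed = min_jerk_profile(30.0, 1.0, 1000.0)
        ldj = ep.log_dimensionless_jerk(speed, 1000.0)
        assert ldj == pytest.approx(MINJERK_LDJ, rel=0.01)
        assert ldj < 0

    def test_invariant_to_amplitude_rescale(self):
        _, _, s1 = min_jerk_profile(10.0, 1.0, 1000.0)
        _, _, s2 = min_jerk_profile(20.0, 1.0, 1000.0)
        a = ep.log_dimensionless_jerk(s1, 1000.0)
        b = ep.log_dimensionless_jerk(s2, 1000.0)
        assert abs(a - b) < 1e-6

    def test_invariant_to_duration_rescale(self):
        # same sample count: time axis dilated, rate halved
        _, _, s1 = min_jerk_profile(10.0, 1.0, 1000.0)
        _, _, s2 = min_jerk_profile(10.0, 2.0, 500.0)
        a = ep.log_dimensionless_jerk(s1, 1000.0)
        b = ep.log_dimensionless_jerk(s2, 500.0)
        assert abs(a - b) < 1e-6

    def test_short_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            ep.log_dimensionless_jerk(np.ones(5), 120.0)

    def test_decreases_with_submovement_count(self):
        ldj = []
        for k in (1, 2, 3, 4):
            t, pos = compose_submovements(
                staircase_schedule(k), 30.0, 2.0, 1000.0
            )
            speed = np.abs(np.gradient(pos, t))
            ldj.append(ep.log_dimensionless_jerk(speed, 1000.0))
        assert ldj[0] > ldj[1] > ldj[2] > ldj[3]

    def test_ranks_smoothness_consistently_with_peak_count(self):
        """NVP and -LDJ order a 50-profile noiseless battery the same way
        (both are smoothness constructs)."""
        rng = np.random.default_rng(6)
        nvp, neg_ldj = [], []
        for i in range(50):
            k = 1 + i % 4
            dur = float(rng.uniform(1.5, 3.0))
            t, pos = compose_submovements(
                staircase_schedule(k), 30.0, dur, 500.0
            )
            speed = np.abs(np.gradient(pos, t))
            nvp.append(ep.count_velocity_peaks(speed, 500.0))
            neg_ldj.append(-ep.log_dimensionless_jerk(speed, 500.0))
        r, _ = spearman(nvp, neg_ldj)
        assert r >= 0.8


class TestRigidMotionInvariance:
    def test_all_parameters_invariant_to_rigid_transform(self, impaired_trial):
        rec, _ = impaired_trial
        prof, _ = extract_profile(rec)

        # arbitrary rigid rotation + translation of the whole marker set
        angle = 0.7
        axis = np.array([0.2, 0.3, 0.93])
        axis = axis / np.linalg.norm(axis)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        shift = np.array([120.0, -40.0, 15.0])

        import dataclasses

        moved = dataclasses.replace(
            rec,
            markers={k: v @ R.T + shift for k, v in rec.markers.items()},
        )
        prof2, _ = extract_profile(moved)
        for name in ("MT", "CurvI", "Vmax", "TpctVmax", "LDJ",
                     "ShFE", "ShAA", "ElFE", "Th", "TExc"):
            assert getattr(prof2, name) == pytest.approx(
                getattr(prof, name), rel=1e-6, abs=1e-6
            ), name
        assert prof2.NVP == prof.NVP
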