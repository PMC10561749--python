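"""Gait parameters: hand-computed cases and simulator ground-truth recovery."""
import math

import numpy as np
import pytest

import gaitagree as g
from gaitagree.config import AnalysisConfig
from gaitagree.parameters import MosParams
from gaitagree.preprocessing import AnalysisWindow, filter_imu, filter_skeleton
from gaitagree.types import (DataError, ImuRecording, InsufficientGaitCycles,
                             GaitEvent, IC, TO, KINEMATIC, LEFT, RIGHT,
                             SkeletonSequence, Stride, TreadmillLog)

from conftest import steady_window


def _belt_const(v, seconds=300.0, rate=64.0):
    t = np.arange(0, seconds, 1 / rate)
    return TreadmillLog(timestamps=t, speed=np.full_like(t, v), rate_hz=rate)


def _detect_all(trial, win, cfg=None, filtered_skel=None):
    cfg = cfg or AnalysisConfig()
    skel = filtered_skel if filtered_skel is not None else \
        filter_skeleton(trial.skeleton, cfg.filter_skeleton)
    kin = g.detect_events_kinematic(skel, win)
    imu = []
    for site in ("FOOT_L", "FOOT_R"):
        imu += g.detect_events_imu(filter_imu(trial.imu(site), cfg.filter_imu), win)
    imu.sort()
    return skel, kin, imu


class TestBeltTranslation:
    def test_constant_speed(self):
        assert g.belt_translation(_belt_const(1.0), 0.0, 1.2) == pytest.approx(1.2, abs=1e-9)

    def test_linear_ramp_triangle_area(self):
        t = np.arange(0, 4, 1 / 64)
        belt = TreadmillLog(timestamps=t, speed=np.clip(t / 2, 0, 1), rate_hz=64)
        assert g.belt_translation(belt, 0.0, 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_zero_width_interval(self):
        assert g.belt_translation(_belt_const(1.0), 1.0, 1.0) == 0.0

    def test_interval_outside_log_rejected(self):
        with pytest.raises(DataError):
            g.belt_translation(_belt_const(1.0, seconds=10), 5.0, 20.0)


class TestStrideTime:
    def test_hand_case(self):
        s = [Stride(side=LEFT, t_ic=0.3, t_ic_next=1.5)]
        assert g.stride_time(s)[0] == pytest.approx(1.2)

    def test_simulation_mean_recovery(self, clean_trial):
        win = steady_window(clean_trial)
        _, kin, _ = _detect_all(clean_trial, win)
        st = g.stride_time(g.pair_strides(kin))
        n = len(st)
        assert abs(np.mean(st) - 1.1) <= (1 / 30) / math.sqrt(n)

    def test_jittered_stride_time_sd_recovered(self):
        """With stride-time CV 0.03 the detected stride-time SD matches the
        simulator's injected dispersion within 20% (n >= 50 strides)."""
        p = g.GaitProfile(stride_cv=0.03)
        trial = g.simulate_trial(p, duration_walk=70.0, seed=5)
        win = steady_window(trial)
        _, kin, imu = _detect_all(trial, win)
        st = g.stride_time(g.pair_strides(imu))
        assert len(st) >= 50
        periods = trial.truth.stride_period_log
        true_sd = np.std(periods[(periods > 0)])
        assert abs(np.std(st) - true_sd) / true_sd < 0.20


class TestStrideLengthKinematic:
    def _skel_fixed_ankle(self, z_by_time):
        t = np.arange(0, 4, 1 / 30)
        zeros = np.zeros_like(t)
        z = np.interp(t, *zip(*z_by_time))
        joints = {
            "PELVIS": np.column_stack([zeros, zeros + 0.9, zeros]),
            "ANKLE_L": np.column_stack([zeros - 0.06, zeros, z]),
            "ANKLE_R": np.column_stack([zeros + 0.06, zeros, zeros]),
        }
        return SkeletonSequence(timestamps=t, joints=joints)

    def test_pure_belt_term(self):
        skel = self._skel_fixed_ankle([(0, 0.3), (4, 0.3)])
        strides = [Stride(side=LEFT, t_ic=1.0, t_ic_next=2.2)]
        out = g.stride_length_kinematic(skel, strides, _belt_const(1.0))
        assert out[0] == pytest.approx(1.2, abs=1e-9)

    def test_ankle_drift_adds(self):
        skel = self._skel_fixed_ankle([(0, 0.3), (4, 0.32)])  # +5 mm/s drift
        strides = [Stride(side=LEFT, t_ic=1.0, t_ic_next=2.2)]
        out = g.stride_length_kinematic(skel, strides, _belt_const(1.0))
        assert out[0] == pytest.approx(1.2 + 0.005 * 1.2, abs=1e-6)

    def test_simulation_per_stride_within_1cm(self, clean_trial):
        win = steady_window(clean_trial)
        skel, kin, _ = _detect_all(clean_trial, win)
        strides = g.pair_strides(kin)
        sl = g.stride_length_kinematic(skel, strides, clean_trial.belt)
        expected = clean_trial.profile.belt_speed * clean_trial.profile.stride_time
        assert np.nanmax(np.abs(sl - expected)) < 0.01


class TestStrideLengthImu:
    def test_constant_acceleration_hand_case(self):
        """a = 2 m/s² over 1 s from rest with a stopped belt: d = a t²/2 = 1 m."""
        t = np.arange(0, 2, 1 / 128)
        accel = np.zeros((len(t), 3))
        accel[:, 2] = 2.0
        rec = ImuRecording(site="FOOT_L", timestamps=t, accel=accel,
                           gyro=np.zeros_like(accel))
        belt = TreadmillLog(timestamps=np.arange(0, 3, 1 / 64),
                            speed=np.zeros(192), rate_hz=64)
        strides = [Stride(side=LEFT, t_ic=0.0, t_ic_next=1.0, t_to=0.0)]
        out = g.stride_length_imu(rec, strides, belt, dedrift=False)
        assert out[0] == pytest.approx(1.0, abs=1e-3)

    def test_simulation_per_stride_within_1cm(self, clean_trial):
        win = steady_window(clean_trial)
        _, _, imu = _detect_all(clean_trial, win)
        strides = g.pair_strides(imu)
        expected = clean_trial.profile.belt_speed * clean_trial.profile.stride_time
        for site in ("FOOT_L", "FOOT_R"):
            sl = g.stride_length_imu(clean_trial.imu(site), strides, clean_trial.belt)
            vals = sl[~np.isnan(sl)]
            assert len(vals) >= 20
            assert np.max(np.abs(vals - expected)) < 0.01

    def test_bias_injection_dedrift_helps(self, clean_trial):
        """An additive 0.05 m/s² accelerometer bias is absorbed by the linear
        velocity dedrift; without it the error grows with swing duration."""
        win = steady_window(clean_trial)
        _, _, imu = _detect_all(clean_trial, win)
        strides = g.pair_strides(imu)
        rec = clean_trial.imu("FOOT_L")
        biased = ImuRecording(site=rec.site, timestamps=rec.timestamps,
                              accel=rec.accel + np.array([0, 0, 0.05]),
                              gyro=rec.gyro, rate_hz=rec.rate_hz)
        expected = clean_trial.profile.belt_speed * clean_trial.profile.stride_time
        on = g.stride_length_imu(biased, strides, clean_trial.belt, dedrift=True)
        off = g.stride_length_imu(biased, strides, clean_trial.belt, dedrift=False)
        err_on = np.nanmean(np.abs(on - expected))
        err_off = np.nanmean(np.abs(off - expected))
        assert err_on < 0.02
        assert err_off > err_on

    def test_missing_to_excluded(self):
        rec = ImuRecording(site="FOOT_L", timestamps=np.arange(0, 2, 1 / 128),
                           accel=np.zeros((256, 3)), gyro=np.zeros((256, 3)))
        strides = [Stride(side=LEFT, t_ic=0.0, t_ic_next=1.0)]
        out = g.stride_length_imu(rec, strides, _belt_const(1.0))
        assert np.isnan(out[0])


class TestSupportTimes:
    def test_closed_forms_from_imu_events(self, clean_trial):
        """Symmetric gait, duty d: single support = (1−d)T, double support
        = (2d−1)T; the inertial events recover both within one 30 Hz frame."""
        win = steady_window(clean_trial)
        _, _, imu = _detect_all(clean_trial, win)
        single, double = g.support_times(g.pair_strides(imu))
        T, d = 1.1, 0.6
        assert abs(np.nanmean(single) - (1 - d) * T) < 1 / 30
        assert abs(np.nanmean(double) - (2 * d - 1) * T) < 1 / 30

    def test_kinematic_support_times_biased_inward(self, clean_trial):
        """Extremum-based camera events sit inside the contact phase, so
        camera single support is biased short — the known weakness of
        support times from the depth camera."""
        win = steady_window(clean_trial)
        _, kin, _ = _detect_all(clean_trial, win)
        single, _ = g.support_times(g.pair_strides(kin))
        bias = np.nanmean(single) - 0.4 * 1.1
        assert -0.08 < bias < 0.0

    def test_walking_running_boundary(self):
        """As duty factor approaches 0.5 double support vanishes."""
        d, T = 0.501, 1.0
        events = []
        for k in range(3):
            events += [GaitEvent(k * T, LEFT, IC, KINEMATIC),
                       GaitEvent(k * T + d * T, LEFT, TO, KINEMATIC),
                       GaitEvent(k * T + 0.5 * T, RIGHT, IC, KINEMATIC),
                       GaitEvent(k * T + 0.5 * T + d * T, RIGHT, TO, KINEMATIC)]
        single, double = g.support_times(g.pair_strides(sorted(events)))
        assert np.nanmean(single) == pytest.approx((1 - d) * T, abs=1e-9)
        assert np.nanmean(double) == pytest.approx((2 * d - 1) * T, abs=1e-9)

    def test_left_only_events_give_nan_not_crash(self):
        events = [GaitEvent(t, LEFT, k, KINEMATIC)
                  for t, k in [(0.0, IC), (0.6, TO), (1.0, IC), (1.6, TO), (2.0, IC)]]
        single, double = g.support_times(g.pair_strides(events))
        assert np.all(np.isnan(single)) and np.all(np.isnan(double))


class TestCadence:
    def test_hand_case(self):
        events = [GaitEvent(t, LEFT if i % 2 else RIGHT, IC, KINEMATIC)
                  for i, t in enumerate(np.linspace(0, 59.5, 120))]
        assert g.cadence(events, AnalysisWindow(0, 60)) == pytest.approx(120.0)

    def test_simulation(self):
        trial = g.simulate_trial(g.GaitProfile(stride_time=1.2, belt_speed=1.0),
                                 duration_walk=40.0, seed=2)
        win = steady_window(trial)
        _, kin, _ = _detect_all(trial, win)
        assert g.cadence(kin, win) == pytest.approx(100.0, abs=1.0)

    def test_empty_window_raises(self, clean_trial):
        with pytest.raises(InsufficientGaitCycles):
            g.cadence([], AnalysisWindow(0, 10))


class TestStepWidth:
    def test_hand_case(self):
        t = np.arange(0, 2, 1 / 30)
        zeros = np.zeros_like(t)
        joints = {
            "PELVIS": np.column_stack([zeros, zeros, zeros]),
            "ANKLE_L": np.column_stack([zeros - 0.06, zeros, zeros]),
            "ANKLE_R": np.column_stack([zeros + 0.06, zeros, zeros]),
        }
        skel = SkeletonSequence(timestamps=t, joints=joints)
        out = g.step_width(skel, [Stride(side=LEFT, t_ic=0.5, t_ic_next=1.5)])
        assert out[0] == pytest.approx(0.12, abs=1e-12)

    def test_simulation_recovery(self, clean_trial):
        win = steady_window(clean_trial)
        skel, kin, _ = _detect_all(clean_trial, win)
        sw = g.step_width(skel, g.pair_strides(kin))
        assert abs(np.nanmean(sw) - clean_trial.truth.step_width) < 0.005

    def test_single_side_absent(self):
        t = np.arange(0, 2, 1 / 30)
        zeros = np.zeros_like(t)
        joints = {"PELVIS": np.column_stack([zeros, zeros, zeros]),
                  "ANKLE_L": np.column_stack([zeros, zeros, zeros])}
        skel = SkeletonSequence(timestamps=t, joints=joints)
        out = g.step_width(skel, [Stride(side=LEFT, t_ic=0.5, t_ic_next=1.5)])
        assert np.isnan(out[0])


class TestMarginOfStability:
    def _static_skel(self, pelvis_x):
        t = np.arange(0, 1, 1 / 30)
        n = len(t)
        joints = {
            "PELVIS": np.column_stack([pelvis_x(t), np.full(n, 0.9), np.zeros(n)]),
            "ANKLE_R": np.tile([0.10, 0.08, 0.30], (n, 1)),
            "ANKLE_L": np.tile([-0.10, 0.08, 0.30], (n, 1)),
            "TOE_R": np.tile([0.10, 0.03, 0.45], (n, 1)),
        }
        return SkeletonSequence(timestamps=t, joints={k: np.asarray(v, float)
                                                      for k, v in joints.items()})

    def test_static_limit_is_geometric_distance(self):
        """Zero CoM velocity: MoS equals the CoM-to-BoS distance exactly."""
        skel = self._static_skel(lambda t: np.zeros_like(t))
        s = [Stride(side=RIGHT, t_ic=0.5, t_ic_next=0.9)]
        ml, ap = g.margin_of_stability(skel, s, MosParams(l=0.981))
        assert ml[0] == pytest.approx(0.10, abs=1e-12)
        assert ap[0] == pytest.approx(0.45, abs=1e-12)

    def test_velocity_offset_hand_case(self):
        """v = 0.31623 m/s towards the foot with ω₀ = 3.1623 s⁻¹ shifts the
        XCoM by 0.10 m, cancelling the geometric margin."""
        skel = self._static_skel(lambda t: 0.31623 * (t - 0.5))
        s = [Stride(side=RIGHT, t_ic=0.5, t_ic_next=0.9)]
        ml, _ = g.margin_of_stability(skel, s, MosParams(l=0.981))
        assert ml[0] == pytest.approx(0.0, abs=1e-4)

    def test_missing_toe_gives_nan_ap(self):
        skel = self._static_skel(lambda t: np.zeros_like(t))
        s = [Stride(side=LEFT, t_ic=0.5, t_ic_next=0.9)]  # no TOE_L joint
        ml, ap = g.margin_of_stability(skel, s, MosParams(l=0.981))
        assert np.isfinite(ml[0]) and np.isnan(ap[0])

    def test_noisy_skeleton_matches_true_com_oracle(self):
        """MoS from a 3 mm-noise skeleton agrees with MoS recomputed from the
        recorded true CoM trajectory within 1 cm (window average)."""
        p = g.GaitProfile(noise_skeleton_m=0.003)
        trial = g.simulate_trial(p, duration_walk=40.0, seed=9)
        cfg = AnalysisConfig()
        win = steady_window(trial)
        skel, kin, _ = _detect_all(trial, win, cfg)
        strides = g.pair_strides(kin)
        mos = MosParams(l=trial.profile.leg_length)
        ml_noisy, _ = g.margin_of_stability(skel, strides, mos)
        # oracle: same strides, same (noise-free) feet, true CoM as pelvis
        clean = g.simulate_trial(g.GaitProfile(), duration_walk=40.0, seed=9)
        oracle_joints = dict(clean.skeleton.joints)
        oracle_joints["PELVIS"] = clean.truth.com_traj
        oracle = SkeletonSequence(timestamps=clean.skeleton.timestamps,
                                  joints=oracle_joints)
        ml_true, _ = g.margin_of_stability(
            filter_skeleton(oracle, cfg.filter_skeleton), strides, mos)
        assert abs(np.nanmean(ml_noisy) - np.nanmean(ml_true)) < 0.01


class TestArmSwing:
    def test_imu_analytic_sinusoid(self):
        """ω = A(2π/T)cos(2πt/T) integrates to amplitude 2A peak-to-peak."""
        A = math.radians(15.0)
        T = 1.1
        t = np.arange(0, 30, 1 / 128)
        gyro = np.zeros((len(t), 3))
        gyro[:, 0] = A * (2 * np.pi / T) * np.cos(2 * np.pi * t / T)
        rec = ImuRecording(site="WRIST_L", timestamps=t, accel=np.zeros_like(gyro),
                           gyro=gyro)
        amps = g.arm_swing_imu(rec, AnalysisWindow(0, 30))
        assert np.mean(amps) == pytest.approx(30.0, abs=0.5)

    def test_zero_gyro_zero_amplitude(self):
        t = np.arange(0, 5, 1 / 128)
        rec = ImuRecording(site="WRIST_L", timestamps=t,
                           accel=np.zeros((len(t), 3)), gyro=np.zeros((len(t), 3)))
        assert g.arm_swing_imu(rec, AnalysisWindow(0, 5))[0] == 0.0

    def test_simulation_gyro_recovery(self):
        p = g.GaitProfile(arm_swing_deg_l=40.0, arm_swing_deg_r=40.0)
        trial = g.simulate_trial(p, duration_walk=40.0, seed=4)
        cfg = AnalysisConfig()
        win = steady_window(trial)
        for site in ("WRIST_L", "WRIST_R"):
            amps = g.arm_swing_imu(filter_imu(trial.imu(site), cfg.filter_imu), win)
            assert abs(np.mean(amps) - 40.0) < 1.0

    def _pendulum_skel(self, amp_deg, r=1.0, T=1.2, seconds=12.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, seconds, 1 / 30)
        alpha = math.radians(amp_deg / 2) * np.sin(2 * np.pi * t / T)
        shoulder = np.column_stack([np.zeros_like(t), np.full_like(t, 1.4),
                                    np.zeros_like(t)])
        wrist = shoulder + np.column_stack([np.zeros_like(t),
                                            -r * np.cos(alpha), r * np.sin(alpha)])
        if noise:
            wrist = wrist + rng.normal(0, noise, wrist.shape)
        zeros = np.zeros_like(t)
        joints = {"PELVIS": np.column_stack([zeros, zeros, zeros]),
                  "ANKLE_L": np.column_stack([zeros, zeros, zeros]),
                  "ANKLE_R": np.column_stack([zeros, zeros, zeros]),
                  "SHOULDER_L": shoulder, "WRIST_L": wrist}
        return SkeletonSequence(timestamps=t, joints=joints)

    def test_kinematic_right_angle_chord(self):
        """Pendulum of amplitude 90°: chord = √2·r, law of cosines gives 90°."""
        skel = self._pendulum_skel(90.0)
        amps = g.arm_swing_kinematic(skel, AnalysisWindow(0, 12), LEFT)
        assert np.mean(amps) == pytest.approx(90.0, abs=2.0)

    def test_kinematic_degenerate_chords(self):
        # c = 0: motionless wrist
        skel = self._pendulum_skel(0.0)
        assert g.arm_swing_kinematic(skel, AnalysisWindow(0, 12), LEFT)[0] == 0.0

    def test_kinematic_chord_clamped_at_diameter(self):
        """Wrist positions alternating between r and 3r from the shoulder:
        the chord exceeds the 2r̃ diameter and clamps to 180°."""
        t = np.arange(0, 8, 1 / 30)
        z = np.where((t // 1.0) % 2 == 0, 1.0, -3.0)  # alternates every 1 s
        shoulder = np.column_stack([np.zeros_like(t), np.zeros_like(t), np.zeros_like(t)])
        wrist = np.column_stack([np.zeros_like(t), np.zeros_like(t), z])
        zeros = np.zeros_like(t)
        joints = {"PELVIS": np.column_stack([zeros, zeros, zeros]),
                  "ANKLE_L": np.column_stack([zeros, zeros, zeros]),
                  "ANKLE_R": np.column_stack([zeros, zeros, zeros]),
                  "SHOULDER_L": shoulder, "WRIST_L": wrist}
        skel = SkeletonSequence(timestamps=t, joints=joints)
        amps = g.arm_swing_kinematic(skel, AnalysisWindow(0, 8), LEFT)
        assert np.all(amps == pytest.approx(180.0))

    def test_kinematic_noise_inflation_matches_mc_oracle(self):
        """25 mm wrist noise inflates the chord-based amplitude; the bias
        matches a Monte-Carlo expectation of chord inflation under isotropic
        Gaussian noise at the wrist extremes."""
        amp, r, sigma, T = 40.0, 0.6, 0.025, 1.2
        skel = self._pendulum_skel(amp, r=r, T=T, seconds=60.0, noise=sigma, seed=3)
        measured = float(np.mean(g.arm_swing_kinematic(skel, AnalysisWindow(0, 60), LEFT)))
        # Monte-Carlo oracle: sample the pendulum path at 30 Hz around each
        # extreme, perturb isotropically, and select the extreme-most noisy
        # sample per half-cycle (the selection an extremum picker performs),
        # then apply the law of cosines to the resulting chords.
        rng = np.random.default_rng(0)
        a0 = math.radians(amp / 2)
        tq = np.arange(0, T / 2, 1 / 30)  # samples of one half-cycle
        alpha_max = a0 * np.sin(2 * np.pi * (tq - 0.0) / T + np.pi / 2)
        pts_max = np.column_stack([np.zeros_like(tq), -r * np.cos(alpha_max),
                                   r * np.sin(alpha_max)])
        pts_min = pts_max * np.array([1.0, 1.0, -1.0])  # mirrored half-cycle
        exp = []
        for _ in range(4000):
            n1 = pts_max + rng.normal(0, sigma, pts_max.shape)
            n2 = pts_min + rng.normal(0, sigma, pts_min.shape)
            w1 = n1[np.argmax(n1[:, 2])]
            w2 = n2[np.argmin(n2[:, 2])]
            c = min(float(np.linalg.norm(w1 - w2)), 2 * r)
            exp.append(math.degrees(math.acos((2 * r * r - c * c) / (2 * r * r))))
        exp_amp = float(np.mean(exp))
        assert measured > amp  # biased high
        assert abs(measured - exp_amp) < 1.5


class TestSummarize:
    def test_mean_of_two_strides(self):
        import pandas as pd
        table = pd.DataFrame({"side": [LEFT, RIGHT], "stride_time": [1.1, 1.3],
                              "source": KINEMATIC, "ic_time": [0.0, 0.5]})
        row = g.summarize_window(table, AnalysisWindow(0, 10))
        assert row["stride_time"] == pytest.approx(1.2)
        assert row["n_strides"] == 2

    def test_sided_parameter_averaged_within_side(self):
        import pandas as pd
        table = pd.DataFrame({"side": [LEFT, LEFT, RIGHT],
                              "arm_swing": [30.0, 34.0, 20.0],
                              "source": KINEMATIC, "ic_time": [0, 1, 2]})
        row = g.summarize_window(table, AnalysisWindow(0, 10))
        assert row["arm_swing_left"] == pytest.approx(32.0)
        assert row["arm_swing_right"] == pytest.approx(20.0)

    def test_empty_table_raises(self):
        import pandas as pd
        with pytest.raises(InsufficientGaitCycles):
            g.summarize_window(pd.DataFrame(columns=["side", "source"]),
                               AnalysisWindow(0, 10))
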