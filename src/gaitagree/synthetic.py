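"""Synthetic treadmill-gait generator with exact ground truth.

Produces the three device streams of a steady-state treadmill trial — a
30 Hz skeleton sequence, six 128 Hz IMU recordings and a 64 Hz belt-speed
log — for a walker with known gait events and per-stride parameters.  The
trial mirrors the clinical protocol: 3 s of quiet standing, a belt ramp-up,
a long steady-walking phase, belt stop and 3 s of standing.

The kinematic model is deliberately simple but dynamically consistent:

* the stance foot rides the belt (camera-frame velocity = −belt speed);
* the swing-foot anteroposterior velocity is a smooth bump plus two
  narrow Gaussian-CDF transition layers, so the foot leaves the belt at
  −belt speed immediately after toe-off and decelerates back to −belt
  speed just before initial contact.  Every stride lands at a fixed
  per-foot anterior position, so the walker never drifts off the belt and
  the belt-relative stride length is exactly the belt translation per
  stride;
* the pelvis (taken as the centre of mass) sways mediolaterally at stride
  frequency and bounces vertically at twice stride frequency;
* wrists swing about fixed shoulder points in the sagittal plane,
  anti-phase to the ipsilateral leg;
* foot pitch angular velocity is a dominant positive mid-swing lobe with
  narrow negative lobes centred exactly at toe-off and initial contact
  (the signature the foot-IMU event detector keys on).

IMU channels are the analytic derivatives of these trajectories; nothing
is numerically differentiated.  The Gaussian transition layers are chosen
spectrally compact enough that trapezoidal double-integration of the
128 Hz acceleration stream reproduces swing displacement to a few
millimetres, which keeps the stride-length oracle exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .types import (ConfigError, GRAVITY, ImuRecording, LEFT, RIGHT,
                    SkeletonSequence, TreadmillLog,
                    FOOT_L, FOOT_R, WRIST_L, WRIST_R, LUMBAR, STERNUM)

# --- fixed model constants (geometry of the synthetic walker) -------------
_H_ANKLE = 0.08        # ankle height above belt, m
_H_PELVIS = 0.95       # pelvis height, m
_H_SHOULDER = 1.40     # shoulder height, m
_SHOULDER_HALF = 0.18  # half shoulder width, m
_FOOT_LEN = 0.15       # ankle-to-toe length, m
_TOE_DROP = 0.05       # toe below ankle, m
_LAYER_SIGMA = 0.005   # s, width of the swing velocity transition layers
_LAYER_MARGIN = 4 * _LAYER_SIGMA
_PITCH_PEAK = 4.0      # rad/s, mid-swing foot pitch rate
_EVENT_DIP_SIGMA = 0.020  # s, width of the TO/IC gyro dips
_RAMP_S = 3.0          # belt ramp duration, s
_STAND_S = 3.0         # standing bookends, s


def _phi(x):
    """Standard normal pdf."""
    return np.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)


def _Phi(x):
    """Standard normal cdf."""
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


def _iPhi(z):
    """Antiderivative of the standard normal cdf: z Φ(z) + φ(z)."""
    return z * _Phi(z) + _phi(z)


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


@dataclass
class GaitProfile:
    """Gait-cycle parameters of the synthetic walker.

    Defaults sit inside the ranges typical of older adults walking at
    preferred speed on a treadmill; they are configuration, not claims
    about any population.
    """

    belt_speed: float = 1.05        # m/s
    stride_time: float = 1.1        # s, mean cycle period T
    stride_cv: float = 0.0          # stride-time coefficient of variation
    duty_factor: float = 0.60       # stance fraction of the stride
    step_width: float = 0.12        # m, mediolateral ankle separation
    leg_length: float = 0.90        # m (pendulum length)
    pelvis_sway_ml: float = 0.02    # m, ML sway amplitude
    pelvis_bounce_v: float = 0.015  # m, vertical bounce amplitude
    arm_swing_deg_l: float = 30.0   # degrees, peak-to-peak
    arm_swing_deg_r: float = 30.0
    arm_length: float = 0.60        # m, shoulder-to-wrist
    foot_clearance: float = 0.05    # m, mid-swing vertical clearance
    phase_lr: float = 0.5           # left-right phase offset, strides
    noise_skeleton_m: float = 0.0   # per-joint Gaussian SD
    noise_wrist_m: float = 0.0      # wrist joints Gaussian SD
    noise_accel: float = 0.0        # m/s² SD
    noise_gyro: float = 0.0         # rad/s SD

    def __post_init__(self):
        if not 0.0 < self.duty_factor < 1.0:
            raise ConfigError("duty_factor must lie in (0, 1)")
        if self.stride_time <= 0:
            raise ConfigError("stride_time must be positive")
        for name in ("pelvis_sway_ml", "pelvis_bounce_v", "foot_clearance",
                     "step_width", "noise_skeleton_m", "noise_wrist_m",
                     "noise_accel", "noise_gyro", "stride_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Event times and per-stride parameters the simulator guarantees."""

    ic_times: dict[str, np.ndarray]
    to_times: dict[str, np.ndarray]
    stride_times: dict[str, np.ndarray]     # per side, between consecutive ICs
    stride_lengths: dict[str, np.ndarray]   # belt-relative, m
    step_width: float
    arm_swing_deg: dict[str, float]
    com_times: np.ndarray
    com_traj: np.ndarray                    # (n, 3) noise-free pelvis path
    stride_period_log: np.ndarray           # jittered cycle periods, s
    walk_interval: tuple[float, float]      # belt-moving interval, s

    def events_in(self, side: str, kind: str, t0: float, t1: float) -> np.ndarray:
        arr = self.ic_times[side] if kind == "IC" else self.to_times[side]
        return arr[(arr >= t0) & (arr <= t1)]


@dataclass
class SimulatedTrial:
    skeleton: SkeletonSequence
    imus: list[ImuRecording]
    belt: TreadmillLog
    truth: GroundTruth
    profile: GaitProfile

    def imu(self, site: str) -> ImuRecording:
        for rec in self.imus:
            if rec.site == site:
                return rec
        raise KeyError(site)


# ---------------------------------------------------------------------------
# belt profile

class _Belt:
    """Trapezoidal belt-speed profile with closed-form time integral."""

    def __init__(self, v: float, t_on: float, t_off: float, ramp: float):
        # knots of the piecewise-linear speed curve
        self.t = np.array([t_on, t_on + ramp, t_off - ramp, t_off])
        self.v = np.array([0.0, v, v, 0.0])
        # cumulative integral at the knots
        seg = np.diff(self.t) * (self.v[1:] + self.v[:-1]) / 2.0
        self.B = np.concatenate([[0.0], np.cumsum(seg)])

    def speed(self, t):
        return np.interp(t, self.t, self.v)

    def integral(self, t):
        """∫ belt speed dt from trial start to t (vectorized)."""
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(self.t, t, side="right") - 1, 0, len(self.t) - 2)
        dt = np.clip(t - self.t[i], 0.0, None)
        slope = (self.v[i + 1] - self.v[i]) / (self.t[i + 1] - self.t[i])
        out = self.B[i] + self.v[i] * dt + 0.5 * slope * dt * dt
        # beyond the last knot the belt is stopped
        out = np.where(t >= self.t[-1], self.B[-1], out)
        out = np.where(t <= self.t[0], 0.0, out)
        return out


# ---------------------------------------------------------------------------
# foot trajectory

class _FootTrack:
    """Piecewise-analytic anteroposterior/vertical foot trajectory.

    Built from the foot's IC/TO sequence; evaluates position, velocity and
    acceleration at arbitrary times.
    """

    def __init__(self, ics: np.ndarray, tos: np.ndarray, z_front: float,
                 belt: _Belt, clearance_of, t_end: float):
        # segments: ("stance", t0, t1, z_anchor, B_anchor) |
        #           ("swing", t0, t1, params dict)
        self.belt = belt
        self.segments = []
        self.clearance_of = clearance_of
        events = []
        for t in ics:
            events.append((t, "IC"))
        for t in tos:
            events.append((t, "TO"))
        events.sort()
        t_prev = 0.0
        z_prev = z_front  # standing at the landing position
        b_prev = 0.0
        for t, kind in events:
            if kind == "TO":
                # close the running stance at this TO
                self.segments.append(("stance", t_prev, t, z_prev, b_prev))
                self._z_to = z_prev - (float(belt.integral(t)) - b_prev)
                self._t_to = t
            else:  # IC: close the swing started at the last TO
                if not self.segments:  # trajectory starts mid-air: treat as stance
                    self.segments.append(("stance", 0.0, t, z_front, 0.0))
                    t_prev, z_prev, b_prev = t, z_front, float(belt.integral(t))
                    continue
                par = self._swing_params(self._t_to, t, self._z_to, z_front)
                self.segments.append(("swing", self._t_to, t, par))
                t_prev, z_prev, b_prev = t, z_front, float(belt.integral(t))
        # trailing stance to the end of the stream
        self.segments.append(("stance", t_prev, t_end + 1.0, z_prev, b_prev))

    def _swing_params(self, t0: float, t1: float, z0: float, z1: float) -> dict:
        tau = t1 - t0
        sig, m = _LAYER_SIGMA, _LAYER_MARGIN
        v0 = float(self.belt.speed(t0))
        v1 = float(self.belt.speed(t1))
        P = 0.25 * (v0 + v1)  # post-takeoff velocity plateau
        c0, c1 = m, tau - m
        D = z1 - z0
        base_D = (-v0 * tau
                  + (v0 + P) * sig * (_iPhi((tau - c0) / sig) - _iPhi((0 - c0) / sig))
                  - (v1 + P) * sig * (_iPhi((tau - c1) / sig) - _iPhi((0 - c1) / sig)))
        H = (D - base_D) / ((8.0 / 15.0) * tau)
        return dict(tau=tau, v0=v0, v1=v1, P=P, c0=c0, c1=c1, H=H, z0=z0, t0=t0)

    @staticmethod
    def _swing_vel(par, s):
        u = np.clip(s / par["tau"], 0.0, 1.0)
        bump = 16.0 * u * u * (1 - u) * (1 - u)
        return (-par["v0"]
                + (par["v0"] + par["P"]) * _Phi((s - par["c0"]) / _LAYER_SIGMA)
                - (par["v1"] + par["P"]) * _Phi((s - par["c1"]) / _LAYER_SIGMA)
                + par["H"] * bump)

    @staticmethod
    def _swing_acc(par, s):
        u = np.clip(s / par["tau"], 0.0, 1.0)
        dbump = 32.0 * u * (1 - u) * (1 - 2 * u) / par["tau"]
        return ((par["v0"] + par["P"]) * _phi((s - par["c0"]) / _LAYER_SIGMA) / _LAYER_SIGMA
                - (par["v1"] + par["P"]) * _phi((s - par["c1"]) / _LAYER_SIGMA) / _LAYER_SIGMA
                + par["H"] * dbump)

    @staticmethod
    def _swing_pos(par, s):
        sig = _LAYER_SIGMA
        u = np.clip(s / par["tau"], 0.0, 1.0)
        # ∫ bump du closed form: 16(u³/3 − u⁴/2 + u⁵/5); scaled by tau
        ibump = 16.0 * (u ** 3 / 3.0 - u ** 4 / 2.0 + u ** 5 / 5.0) * par["tau"]
        return (par["z0"] - par["v0"] * s
                + (par["v0"] + par["P"]) * sig * (_iPhi((s - par["c0"]) / sig) - _iPhi(-par["c0"] / sig))
                - (par["v1"] + par["P"]) * sig * (_iPhi((s - par["c1"]) / sig) - _iPhi(-par["c1"] / sig))
                + par["H"] * ibump)

    def eval(self, t: np.ndarray):
        """Return (z, vz, az, y_clearance, vy, ay) at times ``t`` (sorted)."""
        z = np.empty_like(t)
        vz = np.empty_like(t)
        az = np.empty_like(t)
        y = np.full_like(t, _H_ANKLE)
        vy = np.zeros_like(t)
        ay = np.zeros_like(t)
        for seg in self.segments:
            kind, t0, t1 = seg[0], seg[1], seg[2]
            i0, i1 = np.searchsorted(t, [t0, t1])
            if i1 <= i0:
                continue
            tt = t[i0:i1]
            if kind == "stance":
                z_anchor, b_anchor = seg[3], seg[4]
                z[i0:i1] = z_anchor - (self.belt.integral(tt) - b_anchor)
                vz[i0:i1] = -self.belt.speed(tt)
                # belt accel: derivative of piecewise-linear speed
                az[i0:i1] = -_num_slope(self.belt, tt)
            else:
                par = seg[3]
                s = tt - par["t0"]
                z[i0:i1] = self._swing_pos(par, s)
                vz[i0:i1] = self._swing_vel(par, s)
                az[i0:i1] = self._swing_acc(par, s)
                u = s / par["tau"]
                c = self.clearance_of(par["t0"] + 0.5 * par["tau"])
                y[i0:i1] = _H_ANKLE + c * np.sin(np.pi * u) ** 2
                vy[i0:i1] = c * (np.pi / par["tau"]) * np.sin(2 * np.pi * u)
                ay[i0:i1] = c * 2 * (np.pi / par["tau"]) ** 2 * np.cos(2 * np.pi * u)
        return z, vz, az, y, vy, ay


def _num_slope(belt: _Belt, t):
    """Slope of the piecewise-linear belt speed at times t."""
    i = np.clip(np.searchsorted(belt.t, t, side="right") - 1, 0, len(belt.t) - 2)
    slope = (belt.v[i + 1] - belt.v[i]) / (belt.t[i + 1] - belt.t[i])
    slope = np.where((t <= belt.t[0]) | (t >= belt.t[-1]), 0.0, slope)
    return slope


# ---------------------------------------------------------------------------
# foot pitch (gyro) model

def _pitch_rate(t: np.ndarray, tos, ics, amp_of) -> np.ndarray:
    """ML angular velocity of the foot: positive mid-swing lobe, negative
    dips centred exactly at TO and IC.  Lobe areas balance so the pitch
    angle returns to zero each stride."""
    w = np.zeros_like(t)
    sig_e = _EVENT_DIP_SIGMA
    for t_to, t_ic in zip(tos, ics):
        tau = t_ic - t_to
        if tau <= 0:
            continue
        amp = amp_of(t_to + 0.5 * tau)
        if amp == 0.0:
            continue
        sig_s = tau / 8.0
        t_mid = t_to + 0.5 * tau
        dip = amp * sig_s / (2.0 * sig_e)  # balances areas
        i0, i1 = np.searchsorted(t, [t_to - 6 * sig_e, t_ic + 6 * sig_e])
        tt = t[i0:i1]
        w[i0:i1] += (amp * np.exp(-0.5 * ((tt - t_mid) / sig_s) ** 2)
                     - dip * np.exp(-0.5 * ((tt - t_to) / sig_e) ** 2)
                     - dip * np.exp(-0.5 * ((tt - t_ic) / sig_e) ** 2))
    return w


def _pitch_angle(t: np.ndarray, tos, ics, amp_of) -> np.ndarray:
    """Closed-form integral of :func:`_pitch_rate` (erf antiderivatives)."""
    th = np.zeros_like(t)
    sig_e = _EVENT_DIP_SIGMA
    s2pi = math.sqrt(2 * math.pi)
    for t_to, t_ic in zip(tos, ics):
        tau = t_ic - t_to
        if tau <= 0:
            continue
        amp = amp_of(t_to + 0.5 * tau)
        if amp == 0.0:
            continue
        sig_s = tau / 8.0
        t_mid = t_to + 0.5 * tau
        dip = amp * sig_s / (2.0 * sig_e)
        i0, i1 = np.searchsorted(t, [t_to - 6 * sig_e, t_ic + 6 * sig_e])
        tt = t[i0:i1]
        th[i0:i1] += (amp * sig_s * s2pi * _Phi((tt - t_mid) / sig_s)
                      - dip * sig_e * s2pi * (_Phi((tt - t_to) / sig_e)
                                              + _Phi((tt - t_ic) / sig_e)))
        # contributions cancel beyond the stride (net area zero)
    return th


# ---------------------------------------------------------------------------
# main entry point

def simulate_trial(profile: GaitProfile, duration_walk: float, seed: int,
                   imu_mode: str = "IDEALIZED") -> SimulatedTrial:
    """Simulate one treadmill trial and return streams plus ground truth.

    ``duration_walk`` is the steady-speed walking duration (the analysis
    window is normally its last 120 s).  ``seed`` fixes every source of
    randomness; identical seeds give bit-identical streams.
    """
    p = profile
    if p.duty_factor * p.stride_time < 2.0 / 30.0:
        raise ConfigError("stance shorter than two skeleton frames: events unresolvable")
    if duration_walk < 3 * p.stride_time:
        raise ConfigError("duration_walk must cover at least a few strides")
    rng = np.random.default_rng(seed)

    t_on = _STAND_S
    t_off = t_on + _RAMP_S + duration_walk + _RAMP_S
    total = t_off + _STAND_S
    belt = _Belt(p.belt_speed, t_on, t_off, _RAMP_S)

    # --- stride timing ----------------------------------------------------
    periods = []
    s_times = [t_on]
    while s_times[-1] < t_off + p.stride_time:
        Tk = p.stride_time * max(0.5, 1.0 + p.stride_cv * rng.standard_normal())
        periods.append(Tk)
        s_times.append(s_times[-1] + Tk)
    s_times = np.asarray(s_times)
    periods = np.asarray(periods)

    d = p.duty_factor
    ic_l = s_times
    to_l = s_times[:-1] + d * periods
    ic_r = s_times[:-1] + p.phase_lr * periods
    to_r = ic_r[:-1] + d * np.diff(ic_r)
    # leading right toe-off of the virtual first right swing
    to_r = np.concatenate([[ic_r[0] - (1 - d) * periods[0]], to_r])

    # walking-motion envelope: amplitudes ramp in/out over ~2 strides
    T0 = p.stride_time

    def env(t):
        t = np.asarray(t, dtype=float)
        up = _smoothstep((t - t_on) / (2 * T0))
        down = 1.0 - _smoothstep((t - (t_off - 2 * T0)) / (2 * T0))
        return up * down

    # --- sampling grids ---------------------------------------------------
    t_sk = np.arange(0.0, total, 1.0 / 30.0)
    t_imu = np.arange(0.0, total, 1.0 / 128.0)
    t_belt = np.arange(0.0, total, 1.0 / 64.0)

    # --- feet -------------------------------------------------------------
    z_front = 0.5 * p.belt_speed * d * p.stride_time  # ahead of pelvis Z=0
    clearance_of = lambda t: p.foot_clearance * float(env(t))
    foot = {}
    for side, ics, tos, x in ((LEFT, ic_l, to_l, -p.step_width / 2),
                              (RIGHT, ic_r, to_r, +p.step_width / 2)):
        foot[side] = dict(track=_FootTrack(ics, tos, z_front, belt, clearance_of, total),
                          ics=ics, tos=tos, x=x)

    # --- pelvis (CoM) -----------------------------------------------------
    # continuous cycle phase: piecewise linear in stride index
    knots = np.concatenate([[0.0], s_times, [total + 1.0]])
    phase_knots = np.concatenate([[0.0], np.arange(len(s_times), dtype=float),
                                  [len(s_times) - 1.0]])

    def cycle_phase(t):
        return np.interp(t, knots, phase_knots)

    def cycle_rate(t):
        i = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, len(knots) - 2)
        dr = (phase_knots[i + 1] - phase_knots[i]) / (knots[i + 1] - knots[i])
        return dr

    def pelvis(t):
        u = cycle_phase(t)
        om = 2 * np.pi * cycle_rate(t)
        e = env(t)
        # sway peaks over the stance foot mid-stance (left stance: X < 0)
        ph_sway = 2 * np.pi * u - (np.pi / 2 + 2 * np.pi * 0.3)
        x = e * p.pelvis_sway_ml * np.sin(ph_sway)
        vx = e * p.pelvis_sway_ml * om * np.cos(ph_sway)
        ax = -e * p.pelvis_sway_ml * om ** 2 * np.sin(ph_sway)
        ph_b = 4 * np.pi * u
        y = _H_PELVIS + e * p.pelvis_bounce_v * np.sin(ph_b)
        vy = e * p.pelvis_bounce_v * 2 * om * np.cos(ph_b)
        ay = -e * p.pelvis_bounce_v * (2 * om) ** 2 * np.sin(ph_b)
        z = np.zeros_like(np.asarray(t, dtype=float))
        return (np.column_stack([x, y, z]),
                np.column_stack([vx, vy, np.zeros_like(vx)]),
                np.column_stack([ax, ay, np.zeros_like(ax)]))

    # --- arms -------------------------------------------------------------
    def arm(t, side):
        amp = math.radians(p.arm_swing_deg_l if side == LEFT else p.arm_swing_deg_r) / 2.0
        ph0 = -np.pi / 2 if side == LEFT else +np.pi / 2
        u = cycle_phase(t)
        om = 2 * np.pi * cycle_rate(t)
        e = env(t)
        alpha = e * amp * np.sin(2 * np.pi * u + ph0)
        dalpha = e * amp * om * np.cos(2 * np.pi * u + ph0)
        ddalpha = -e * amp * om ** 2 * np.sin(2 * np.pi * u + ph0)
        return alpha, dalpha, ddalpha

    def wrist_kinematics(t, side):
        sx = -_SHOULDER_HALF if side == LEFT else _SHOULDER_HALF
        alpha, dal, ddal = arm(t, side)
        L = p.arm_length
        pos = np.column_stack([np.full_like(alpha, sx),
                               _H_SHOULDER - L * np.cos(alpha),
                               L * np.sin(alpha)])
        # second derivative of (−L cos α, L sin α) wrt t
        acc_y = L * (ddal * np.sin(alpha) + dal ** 2 * np.cos(alpha))
        acc_z = L * (ddal * np.cos(alpha) - dal ** 2 * np.sin(alpha))
        acc = np.column_stack([np.zeros_like(alpha), acc_y, acc_z])
        return pos, acc, dal

    # --- skeleton stream --------------------------------------------------
    joints = {}
    pel_pos, _, _ = pelvis(t_sk)
    joints["PELVIS"] = pel_pos
    joints["SHOULDER_L"] = np.column_stack([np.full_like(t_sk, -_SHOULDER_HALF),
                                            np.full_like(t_sk, _H_SHOULDER),
                                            np.zeros_like(t_sk)])
    joints["SHOULDER_R"] = np.column_stack([np.full_like(t_sk, _SHOULDER_HALF),
                                            np.full_like(t_sk, _H_SHOULDER),
                                            np.zeros_like(t_sk)])
    amp_of = {side: (lambda tm, s=side: _PITCH_PEAK * float(env(tm)))
              for side in (LEFT, RIGHT)}
    for side in (LEFT, RIGHT):
        f = foot[side]
        z, vz, az, y, vy, ay = f["track"].eval(t_sk)
        ankle = np.column_stack([np.full_like(t_sk, f["x"]), y, z])
        joints[f"ANKLE_{side[0]}"] = ankle
        theta = _pitch_angle(t_sk, f["tos"], f["ics"][f["ics"] > f["tos"][0]],
                             amp_of[side])
        toe = ankle + np.column_stack([
            np.zeros_like(t_sk),
            -_TOE_DROP * np.cos(theta) + _FOOT_LEN * np.sin(theta),
            _FOOT_LEN * np.cos(theta) + _TOE_DROP * np.sin(theta),
        ])
        joints[f"TOE_{side[0]}"] = toe
        wp, _, _ = wrist_kinematics(t_sk, side)
        joints[f"WRIST_{side[0]}"] = wp

    truth_com = joints["PELVIS"].copy()

    for name in joints:
        sd = p.noise_wrist_m if name.startswith("WRIST") else p.noise_skeleton_m
        if sd > 0:
            joints[name] = joints[name] + rng.normal(0.0, sd, joints[name].shape)

    skel = SkeletonSequence(timestamps=t_sk, joints=joints, rate_hz=30.0)

    # --- IMU streams ------------------------------------------------------
    imus = []
    pitch_by_site = {}
    for side, site in ((LEFT, FOOT_L), (RIGHT, FOOT_R)):
        f = foot[side]
        z, vz, az, y, vy, ay = f["track"].eval(t_imu)
        accel = np.column_stack([np.zeros_like(t_imu), ay, az])
        land_ics = f["ics"][f["ics"] > f["tos"][0]]
        gx = _pitch_rate(t_imu, f["tos"], land_ics, amp_of[side])
        gyro = np.column_stack([gx, np.zeros_like(t_imu), np.zeros_like(t_imu)])
        pitch_by_site[site] = _pitch_angle(t_imu, f["tos"], land_ics, amp_of[side])
        imus.append(_finish_imu(site, t_imu, accel, gyro, pitch_by_site[site],
                                imu_mode, rng, p))
    for side, site in ((LEFT, WRIST_L), (RIGHT, WRIST_R)):
        _, acc, dal = wrist_kinematics(t_imu, side)
        gyro = np.column_stack([dal, np.zeros_like(t_imu), np.zeros_like(t_imu)])
        alpha, _, _ = arm(t_imu, side)
        imus.append(_finish_imu(site, t_imu, acc, gyro, alpha, imu_mode, rng, p))
    _, _, pel_acc = pelvis(t_imu)
    zero3 = np.zeros((len(t_imu), 3))
    for site in (LUMBAR, STERNUM):
        imus.append(_finish_imu(site, t_imu, pel_acc.copy(), zero3.copy(),
                                np.zeros_like(t_imu), imu_mode, rng, p))

    # --- belt log ---------------------------------------------------------
    belt_log = TreadmillLog(timestamps=t_belt, speed=belt.speed(t_belt), rate_hz=64.0)

    # --- ground truth -----------------------------------------------------
    ic_times, to_times, st_times, st_lens = {}, {}, {}, {}
    for side in (LEFT, RIGHT):
        f = foot[side]
        land_ics = f["ics"][f["ics"] > f["tos"][0]]  # ICs that end a swing
        ic_times[side] = land_ics
        to_times[side] = f["tos"]
        ics_all = f["ics"]
        st_times[side] = np.diff(ics_all)
        st_lens[side] = np.diff(belt.integral(ics_all))
    truth = GroundTruth(
        ic_times=ic_times, to_times=to_times,
        stride_times=st_times, stride_lengths=st_lens,
        step_width=p.step_width,
        arm_swing_deg={LEFT: p.arm_swing_deg_l, RIGHT: p.arm_swing_deg_r},
        com_times=t_sk, com_traj=truth_com,
        stride_period_log=periods,
        walk_interval=(t_on, t_off),
    )
    return SimulatedTrial(skeleton=skel, imus=imus, belt=belt_log,
                          truth=truth, profile=p)


def _finish_imu(site, t, accel, gyro, pitch, mode, rng, p: GaitProfile) -> ImuRecording:
    accel, gyro = imu_sensor_frame(accel, gyro, pitch, mode)
    if p.noise_accel > 0:
        accel = accel + rng.normal(0.0, p.noise_accel, accel.shape)
    if p.noise_gyro > 0:
        gyro = gyro + rng.normal(0.0, p.noise_gyro, gyro.shape)
    return ImuRecording(site=site, timestamps=t, accel=accel, gyro=gyro, rate_hz=128.0)


def imu_sensor_frame(world_accel: np.ndarray, world_gyro: np.ndarray,
                     orientation_pitch: np.ndarray, mode: str = "IDEALIZED"):
    """Convert world-aligned, gravity-free IMU channels to the sensor frame.

    ``IDEALIZED`` returns the channels untouched (world-aligned,
    gravity-free — the exact-oracle convention).  ``REALISTIC`` rotates
    into a sensor frame pitched about the mediolateral (X) axis by
    ``orientation_pitch`` and adds gravity, so a stationary flat sensor
    reads +g on its vertical channel.
    """
    if mode == "IDEALIZED":
        return world_accel, world_gyro
    if mode != "REALISTIC":
        raise ConfigError(f"unknown IMU mode {mode!r}")
    th = np.asarray(orientation_pitch, dtype=float)
    c, s = np.cos(th), np.sin(th)
    f_world = world_accel + np.array([0.0, GRAVITY, 0.0])  # specific force
    # sensor frame = world frame rotated by pitch about X:
    #   y_s =  c*y_w − s*z_w ;  z_s = s*y_w + c*z_w  (x unchanged)
    ax = f_world[:, 0]
    ay = c * f_world[:, 1] - s * f_world[:, 2]
    az = s * f_world[:, 1] + c * f_world[:, 2]
    gx = world_gyro[:, 0]
    gy = c * world_gyro[:, 1] - s * world_gyro[:, 2]
    gz = s * world_gyro[:, 1] + c * world_gyro[:, 2]
    return np.column_stack([ax, ay, az]), np.column_stack([gx, gy, gz])
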