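"""Spatiotemporal and stability gait parameters, per stride and per window.

Every parameter is computed independently for each modality that can supply
it.  Stride time, stride length, support times and cadence exist for both
modalities; step width and the margin of stability need spatial relations
between body parts and are kinematic-only, while arm swing has one
estimator per modality.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .preprocessing import AnalysisWindow
from .types import (DataError, GaitEvent, GRAVITY, IC, InsufficientGaitCycles,
                    LEFT, RIGHT, SIDES, STRIDE_COLUMNS, SkeletonSequence,
                    Stride, TreadmillLog, ImuRecording)

log = logging.getLogger("gaitagree")


@dataclass
class MosParams:
    """Inverted-pendulum constants for the extrapolated centre of mass.

    ``l`` is the pendulum length (leg length, or the mean ankle-to-pelvis
    distance at initial contacts when no leg length is known);
    the eigenfrequency is ω₀ = √(g/l).
    """

    l: float
    g: float = GRAVITY

    def __post_init__(self):
        if self.l <= 0:
            raise ValueError("pendulum length must be positive")

    @property
    def omega0(self) -> float:
        return math.sqrt(self.g / self.l)


# ---------------------------------------------------------------------------
# temporal / spatial basics

def belt_translation(belt: TreadmillLog, t0: float, t1: float) -> float:
    """Belt travel (m) over [t0, t1]: trapezoidal integral of belt speed."""
    if t1 < t0:
        raise DataError("belt_translation needs t0 <= t1")
    if t0 < belt.timestamps[0] - 1e-9 or t1 > belt.timestamps[-1] + 1e-9:
        raise DataError("interval outside the belt log")
    if t1 == t0:
        return 0.0
    inner = belt.timestamps[(belt.timestamps > t0) & (belt.timestamps < t1)]
    ts = np.concatenate([[t0], inner, [t1]])
    return float(np.trapezoid(belt.speed_at(ts), ts))


def stride_time(strides: list[Stride]) -> np.ndarray:
    """Ipsilateral IC-to-IC duration per stride (s)."""
    return np.array([s.stride_time for s in strides])


def _track_at(skel: SkeletonSequence, joint: str, times, axis: int) -> np.ndarray:
    return np.interp(times, skel.timestamps, skel.joints[joint][:, axis])


def stride_length_kinematic(skel: SkeletonSequence, strides: list[Stride],
                            belt: TreadmillLog) -> np.ndarray:
    """Camera stride length: anteroposterior ankle displacement between
    consecutive ICs plus the belt translation over the stride."""
    out = np.full(len(strides), np.nan)
    for i, s in enumerate(strides):
        joint = f"ANKLE_{s.side[0]}"
        if joint not in skel.joints:
            continue
        z0 = _track_at(skel, joint, s.t_ic, 2)
        z1 = _track_at(skel, joint, s.t_ic_next, 2)
        out[i] = (z1 - z0) + belt_translation(belt, s.t_ic, s.t_ic_next)
    return out


def stride_length_imu(foot: ImuRecording, strides: list[Stride],
                      belt: TreadmillLog, ap_axis: int = 2,
                      dedrift: bool = True,
                      belt_interval_full_stride: bool = False) -> np.ndarray:
    """Inertial stride length by swing-phase double integration.

    The anteroposterior acceleration between each toe-off and the next
    ipsilateral initial contact is integrated twice, starting from the
    foot's known camera-frame velocity on the belt, v(TO) = −belt speed;
    the swing displacement plus the belt translation gives the stride
    length.  ``dedrift`` applies a linear velocity correction so that the
    reconstructed velocity at IC equals −belt speed (a zero-velocity-update
    analogue that absorbs additive accelerometer bias).

    Only strides of the recording's own side get values; others stay NaN.
    The acceleration stream is integrated as recorded (unfiltered):
    low-passing redistributes the landing transient across the integration
    boundary and biases the estimate, while integration itself already
    suppresses high-frequency noise.
    """
    side = LEFT if foot.site.endswith("_L") else RIGHT
    out = np.full(len(strides), np.nan)
    for i, s in enumerate(strides):
        if s.side != side or s.t_to is None:
            continue
        m = (foot.timestamps >= s.t_to) & (foot.timestamps <= s.t_ic_next)
        t = foot.timestamps[m]
        if len(t) < 4:
            continue
        a = foot.accel[m, ap_axis]
        v = -belt.speed_at(s.t_to) + np.concatenate(
            [[0.0], cumulative_trapezoid(a, t)])
        if dedrift:
            target = -belt.speed_at(s.t_ic_next)
            v = v + (target - v[-1]) * (t - t[0]) / (t[-1] - t[0])
        d = float(np.trapezoid(v, t))
        if belt_interval_full_stride:
            out[i] = d + belt_translation(belt, s.t_ic, s.t_ic_next)
        else:
            out[i] = d + belt_translation(belt, s.t_to, s.t_ic_next)
    return out


def support_times(strides: list[Stride]) -> tuple[np.ndarray, np.ndarray]:
    """(single support, double support) per stride, in seconds.

    Single support of the stride's side = contralateral swing (contralateral
    TO to contralateral IC inside the stride); double support = the sum of
    the two bilateral-contact intervals.  Strides missing the needed events
    get NaN.
    """
    single = np.full(len(strides), np.nan)
    double = np.full(len(strides), np.nan)
    for i, s in enumerate(strides):
        if s.t_contra_to is not None and s.t_contra_ic is not None \
                and s.t_contra_to < s.t_contra_ic:
            single[i] = s.t_contra_ic - s.t_contra_to
            if s.t_to is not None and s.t_contra_ic < s.t_to:
                double[i] = (s.t_contra_to - s.t_ic) + (s.t_to - s.t_contra_ic)
    return single, double


def cadence(events: list[GaitEvent], window: AnalysisWindow) -> float:
    """Steps per minute: bilateral IC count over the window length."""
    n = sum(1 for e in events
            if e.kind == IC and window.t_start <= e.time <= window.t_end)
    if n == 0 or window.length <= 0:
        raise InsufficientGaitCycles("insufficient gait cycles: no ICs in window")
    return n / window.length * 60.0


def step_width(skel: SkeletonSequence, strides: list[Stride]) -> np.ndarray:
    """Mediolateral ankle separation at each initial contact, per stride.

    Each stride contributes the mean of the widths at its two bounding
    ipsilateral ICs and its interior contralateral IC, when available.
    """
    if "ANKLE_L" not in skel.joints or "ANKLE_R" not in skel.joints:
        return np.full(len(strides), np.nan)
    out = np.full(len(strides), np.nan)
    for i, s in enumerate(strides):
        times = [s.t_ic]
        if s.t_contra_ic is not None:
            times.append(s.t_contra_ic)
        xl = _track_at(skel, "ANKLE_L", times, 0)
        xr = _track_at(skel, "ANKLE_R", times, 0)
        out[i] = float(np.mean(np.abs(xl - xr)))
    return out


# ---------------------------------------------------------------------------
# margin of stability

def com_velocity(skel: SkeletonSequence, joint: str = "PELVIS") -> np.ndarray:
    """Centre-of-mass velocity by central differences on the pelvis track
    (forward/backward differences at the edges)."""
    return np.gradient(skel.joints[joint], skel.timestamps, axis=0)


def margin_of_stability(skel: SkeletonSequence, strides: list[Stride],
                        params: MosParams) -> tuple[np.ndarray, np.ndarray]:
    """(MoS_ML, MoS_AP) at each stride's initial contact.

    The extrapolated centre of mass XCoM = CoM + v_CoM/ω₀ is compared with
    the base of support of the leading foot: mediolaterally the ankle X
    (positive = XCoM medial of the leading ankle), anteroposteriorly the
    toe Z (positive = XCoM behind the toes).  AP values are NaN when the
    toe landmark is absent.
    """
    vel = com_velocity(skel)
    omega0 = params.omega0
    mos_ml = np.full(len(strides), np.nan)
    mos_ap = np.full(len(strides), np.nan)
    for i, s in enumerate(strides):
        t = s.t_ic
        com_x = _track_at(skel, "PELVIS", t, 0)
        com_z = _track_at(skel, "PELVIS", t, 2)
        v_x = np.interp(t, skel.timestamps, vel[:, 0])
        v_z = np.interp(t, skel.timestamps, vel[:, 2])
        xcom_x = com_x + v_x / omega0
        xcom_z = com_z + v_z / omega0
        ankle = f"ANKLE_{s.side[0]}"
        if ankle in skel.joints:
            bound_x = _track_at(skel, ankle, t, 0)
            sign = 1.0 if s.side == RIGHT else -1.0
            mos_ml[i] = sign * (bound_x - xcom_x)
        toe = f"TOE_{s.side[0]}"
        if toe in skel.joints:
            bound_z = _track_at(skel, toe, t, 2)
            mos_ap[i] = bound_z - xcom_z
    return mos_ml, mos_ap


# ---------------------------------------------------------------------------
# arm swing

def arm_swing_imu(wrist: ImuRecording, window: AnalysisWindow) -> np.ndarray:
    """Arm-swing amplitude (degrees, peak-to-peak) per swing cycle from the
    wrist gyro.

    The angular velocity about the dominant rotation axis (first principal
    axis of the gyro covariance in the window) is integrated to an angle,
    linearly dedrifted per cycle; cycles span successive positive-going
    zero crossings of the angular velocity.
    """
    m = window.contains(wrist.timestamps)
    t = wrist.timestamps[m]
    g = wrist.gyro[m]
    if len(t) < 8:
        raise InsufficientGaitCycles("insufficient gait cycles: empty window")
    cov = np.cov(g.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    w = g @ axis
    if float(np.max(np.abs(w))) < 1e-12:
        return np.array([0.0])
    theta = np.concatenate([[0.0], cumulative_trapezoid(w, t)])
    # positive-going zero crossings of w delimit swing cycles
    sign = np.signbit(w)
    crossings = np.flatnonzero(sign[:-1] & ~sign[1:])
    amps = []
    for i0, i1 in zip(crossings[:-1], crossings[1:]):
        seg = theta[i0:i1 + 1]
        if len(seg) < 4:
            continue
        drift = np.linspace(0.0, seg[-1] - seg[0], len(seg))
        seg = seg - seg[0] - drift
        amps.append(float(np.ptp(seg)))
    if not amps:
        return np.array([0.0])
    return np.degrees(np.array(amps))


def arm_swing_kinematic(skel: SkeletonSequence, window: AnalysisWindow,
                        side: str) -> np.ndarray:
    """Arm-swing amplitude (degrees) per cycle from wrist/shoulder positions.

    The arm length r is the median wrist-to-shoulder distance in the
    window; for each successive pair of extreme wrist positions (most
    anterior W₁, most posterior W₂) the chord c = |W₁ − W₂| gives the swing
    angle through the law of cosines, arccos((2r² − c²)/(2r²)).  Chords
    exceeding the 2r diameter (noise) are clamped.
    """
    wrist = f"WRIST_{side[0]}"
    shoulder = f"SHOULDER_{side[0]}"
    skel.require(wrist, shoulder)
    m = window.contains(skel.timestamps)
    w = skel.joints[wrist][m]
    sh = skel.joints[shoulder][m]
    t = skel.timestamps[m]
    if len(t) < 8:
        raise InsufficientGaitCycles("insufficient gait cycles: empty window")
    r = float(np.median(np.linalg.norm(w - sh, axis=1)))
    rel_z = w[:, 2] - sh[:, 2]
    span = float(np.ptp(rel_z))
    if span < 1e-12:
        return np.array([0.0])
    maxima, _ = find_peaks(rel_z, prominence=0.2 * span)
    minima, _ = find_peaks(-rel_z, prominence=0.2 * span)
    extremes = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    amps = []
    clamped = 0
    for (i0, k0), (i1, k1) in zip(extremes[:-1], extremes[1:]):
        if k0 == k1:
            continue
        c = float(np.linalg.norm(w[i1] - w[i0]))
        if c > 2 * r:
            c = 2 * r
            clamped += 1
        amps.append(math.degrees(math.acos((2 * r * r - c * c) / (2 * r * r))))
    if clamped:
        log.info("arm swing %s: clamped %d over-diameter chords", side, clamped)
    if not amps:
        return np.array([0.0])
    return np.array(amps)


# ---------------------------------------------------------------------------
# assembly

def stride_table(strides: list[Stride], source: str, **columns) -> pd.DataFrame:
    """Assemble the per-stride table for one modality.

    ``columns`` maps parameter name -> per-stride array (aligned with
    ``strides``).  Parameters a modality cannot compute are simply absent.
    """
    base = {
        "side": [s.side for s in strides],
        "ic_time": [s.t_ic for s in strides],
        "stride_time": stride_time(strides),
        "source": source,
    }
    base.update(columns)
    df = pd.DataFrame(base)
    order = [c for c in STRIDE_COLUMNS if c in df.columns]
    return df[order + [c for c in df.columns if c not in order]]


def summarize_window(table: pd.DataFrame, window: AnalysisWindow,
                     participant: str = "", extra: dict | None = None) -> dict:
    """Window summary: the arithmetic mean of each parameter over all
    strides (both sides pooled) in the window."""
    if len(table) == 0:
        raise InsufficientGaitCycles("insufficient gait cycles: empty stride table")
    row: dict = {"participant": participant,
                 "source": table["source"].iloc[0],
                 "n_strides": int(len(table)),
                 "window_length_s": window.length}
    for col in table.columns:
        if col in ("side", "source", "ic_time"):
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.notna().any():
            row[col] = float(vals.mean())
    for side in SIDES:  # per-side means for sided parameters
        sub = table[table["side"] == side]
        for col in ("arm_swing",):
            if col in table.columns and len(sub) and sub[col].notna().any():
                row[f"{col}_{side.lower()}"] = float(pd.to_numeric(sub[col]).mean())
    if extra:
        row.update(extra)
    return row
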