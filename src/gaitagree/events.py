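"""Gait-event detection from skeleton kinematics and from foot-IMU gyro.

Two independent detectors produce typed, sided, time-stamped initial
contacts (IC) and toe-offs (TO):

* the position-based detector finds extrema of the anteroposterior ankle
  position relative to the pelvis (foot most anterior = IC, most
  posterior = TO);
* the inertial detector finds the dominant positive mid-swing peak of the
  foot's mediolateral angular velocity and takes the first local minimum
  after it as IC and the last local minimum before it as TO.

Both run a rough peak pass to estimate the stride period, then a
constrained pass with a minimum inter-peak spacing of half the median
stride time.  Outputs always satisfy per-side IC/TO alternation.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.signal import find_peaks

from .preprocessing import AnalysisWindow
from .types import (ConfigError, GaitEvent, IC, IMU, InsufficientGaitCycles,
                    KINEMATIC, LEFT, RIGHT, SIDES, TO, FOOT_L, FOOT_R,
                    ImuRecording, SkeletonSequence, Stride)

log = logging.getLogger("gaitagree")


def _parabolic_refine(y: np.ndarray, i: int, t: np.ndarray) -> float:
    """Sub-sample peak location by parabolic interpolation around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(t[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[min(i + 1, len(t) - 1)] - t[i] if delta >= 0 else t[i] - t[i - 1]
    return float(t[i] + delta * abs(dt))


def _two_pass_peaks(y: np.ndarray, rate_hz: float) -> tuple[np.ndarray, dict]:
    """Rough pass to estimate the stride period, then a constrained pass."""
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        return np.array([], dtype=int), {}
    rough, _ = find_peaks(y, prominence=0.3 * span)
    if len(rough) >= 3:
        median_stride = float(np.median(np.diff(rough))) / rate_hz
    else:
        median_stride = 1.0  # fallback; constrained pass still applies
    distance = max(1, int(round(0.5 * median_stride * rate_hz)))
    peaks, props = find_peaks(y, prominence=0.1 * span, distance=distance)
    return peaks, props


def _enforce_alternation(events: list[tuple[float, str, float]], side: str,
                         source: str) -> list[GaitEvent]:
    """Drop the lesser-prominence event of same-kind consecutive pairs."""
    events = sorted(events)
    out: list[tuple[float, str, float]] = []
    for ev in events:
        if out and out[-1][1] == ev[1]:
            if ev[2] > out[-1][2]:
                out[-1] = ev
        else:
            out.append(ev)
    return [GaitEvent(time=t, side=side, kind=k, source=source) for t, k, _ in out]


def detect_events_kinematic(skel: SkeletonSequence, window: AnalysisWindow,
                            landmark: str = "ANKLE") -> list[GaitEvent]:
    """Position-based IC/TO detection from the skeleton stream.

    Uses the anteroposterior coordinate of the chosen foot landmark relative
    to the pelvis; maxima are ICs, minima TOs.  Peak times are refined to
    sub-frame precision by parabolic interpolation.
    """
    skel.require("PELVIS", f"{landmark}_L", f"{landmark}_R")
    m = window.contains(skel.timestamps)
    t = skel.timestamps[m]
    if len(t) < 4:
        raise InsufficientGaitCycles("insufficient gait cycles: empty window")
    pelvis_z = skel.joints["PELVIS"][m, 2]
    events: list[GaitEvent] = []
    for side in SIDES:
        r = skel.joints[f"{landmark}_{side[0]}"][m, 2] - pelvis_z
        ic_idx, ic_props = _two_pass_peaks(r, skel.rate_hz)
        to_idx, to_props = _two_pass_peaks(-r, skel.rate_hz)
        if len(ic_idx) < 2:
            raise InsufficientGaitCycles(
                f"insufficient gait cycles: {len(ic_idx)} {side} ICs in window")
        tagged = (
            [(_parabolic_refine(r, i, t), IC, p)
             for i, p in zip(ic_idx, ic_props.get("prominences", np.ones(len(ic_idx))))]
            + [(_parabolic_refine(-r, i, t), TO, p)
               for i, p in zip(to_idx, to_props.get("prominences", np.ones(len(to_idx))))]
        )
        tagged = [(tt, k, p) for tt, k, p in tagged
                  if window.t_start <= tt <= window.t_end]
        events.extend(_enforce_alternation(tagged, side, KINEMATIC))
    events.sort()
    log.info("kinematic detector: %d events in window", len(events))
    return events


def detect_events_imu(foot: ImuRecording, window: AnalysisWindow,
                      ml_axis: int = 0, ml_sign: float = 1.0,
                      prominence_frac: float = 0.3,
                      spacing_frac: float = 0.5) -> list[GaitEvent]:
    """IC/TO detection from the foot-mounted gyro's mediolateral channel.

    Swing phases appear as dominant positive peaks of the ML angular
    velocity; IC is the first local minimum after each swing peak, TO the
    last local minimum before it.
    """
    if foot.site not in (FOOT_L, FOOT_R):
        raise ConfigError(f"IMU event detection needs a foot site, got {foot.site}")
    if ml_axis not in (0, 1, 2):
        raise ConfigError("ml_axis must be 0, 1 or 2")
    side = LEFT if foot.site == FOOT_L else RIGHT
    m = window.contains(foot.timestamps)
    t = foot.timestamps[m]
    w = ml_sign * foot.gyro[m, ml_axis]
    if len(t) < 8:
        raise InsufficientGaitCycles("insufficient gait cycles: empty window")

    # rough pass: tall positive peaks only, to estimate swing-peak height
    # and spacing (the swing lobe is the dominant positive feature)
    peak = float(np.max(w))
    if peak <= 0:
        raise InsufficientGaitCycles("insufficient gait cycles: flat gyro signal")
    rough, rough_props = find_peaks(w, height=0.5 * peak)
    if len(rough) < 2:
        raise InsufficientGaitCycles("insufficient gait cycles: no swing peaks")
    median_height = float(np.median(rough_props["peak_heights"]))
    median_stride = float(np.median(np.diff(t[rough])))
    distance = max(1, int(round(spacing_frac * median_stride * foot.rate_hz)))
    swing, _ = find_peaks(w, height=prominence_frac * median_height,
                          prominence=prominence_frac * median_height,
                          distance=distance)
    if len(swing) < 2:
        raise InsufficientGaitCycles("insufficient gait cycles: no swing peaks")

    # ignore shallow ripple minima: keep only dips commensurate with gait
    minima, min_props = find_peaks(-w, prominence=0.1 * median_height)
    tagged: list[tuple[float, str, float]] = []
    for pk in swing:
        before = minima[minima < pk]
        after = minima[minima > pk]
        if len(before):
            i = int(before[-1])
            tagged.append((_parabolic_refine(-w, i, t), TO,
                           float(min_props["prominences"][np.searchsorted(minima, i)])))
        if len(after):
            i = int(after[0])
            tagged.append((_parabolic_refine(-w, i, t), IC,
                           float(min_props["prominences"][np.searchsorted(minima, i)])))
    tagged = [(tt, k, p) for tt, k, p in tagged
              if window.t_start <= tt <= window.t_end]
    events = _enforce_alternation(tagged, side, IMU)
    log.info("imu detector (%s): %d events in window", foot.site, len(events))
    return events


# ---------------------------------------------------------------------------
# stride pairing

def _side_events(events: list[GaitEvent], side: str, kind: str) -> np.ndarray:
    return np.array([e.time for e in events if e.side == side and e.kind == kind])


def pair_strides(events: list[GaitEvent]) -> list[Stride]:
    """Pair consecutive ipsilateral ICs into strides.

    Each stride carries its own TO plus the contralateral IC/TO falling
    inside it, when present.  Incomplete boundary strides are dropped;
    strides lacking an interior event are kept with that field ``None``.
    """
    strides: list[Stride] = []
    for side in SIDES:
        other = RIGHT if side == LEFT else LEFT
        ics = _side_events(events, side, IC)
        tos = _side_events(events, side, TO)
        c_ics = _side_events(events, other, IC)
        c_tos = _side_events(events, other, TO)
        for t0, t1 in zip(ics[:-1], ics[1:]):
            def _inside(arr):
                cand = arr[(arr > t0) & (arr < t1)]
                return float(cand[0]) if len(cand) else None

            strides.append(Stride(side=side, t_ic=t0, t_ic_next=t1,
                                  t_to=_inside(tos),
                                  t_contra_ic=_inside(c_ics),
                                  t_contra_to=_inside(c_tos)))
    strides.sort(key=lambda s: s.t_ic)
    return strides
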