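"""Filtering, trimming of non-walking segments and analysis-window selection."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, lfilter

from .config import FilterSpec
from .types import ConfigError, DataError, ImuRecording, SkeletonSequence, TreadmillLog

log = logging.getLogger("gaitagree")


@dataclass
class AnalysisWindow:
    """Shared-wall-clock analysis interval (nominally the last 120 s of walking)."""

    t_start: float
    t_end: float

    @property
    def length(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t) -> np.ndarray:
        return (np.asarray(t) >= self.t_start) & (np.asarray(t) <= self.t_end)


def butterworth_lowpass(signal: np.ndarray, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    """Low-pass Butterworth filter of one uniformly sampled channel.

    With ``spec.zero_phase`` the filter runs forward and backward
    (zero group delay; the stated order is the per-pass design order).
    """
    signal = np.asarray(signal, dtype=float)
    if spec.cutoff_hz >= rate_hz / 2:
        raise ConfigError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({rate_hz / 2} Hz)")
    if len(signal) <= 3 * spec.order:
        raise ConfigError("signal too short for the requested filter order")
    if not np.all(np.isfinite(signal)):
        raise DataError("cannot filter non-finite samples")
    b, a = butter(spec.order, spec.cutoff_hz / (rate_hz / 2.0))
    if spec.zero_phase:
        return filtfilt(b, a, signal)
    return lfilter(b, a, signal)


def filter_skeleton(skel: SkeletonSequence, spec: FilterSpec) -> SkeletonSequence:
    """Filter every joint coordinate channel."""
    joints = {}
    for name, arr in skel.joints.items():
        out = np.empty_like(arr)
        for c in range(3):
            out[:, c] = butterworth_lowpass(arr[:, c], spec, skel.rate_hz)
        joints[name] = out
    return SkeletonSequence(timestamps=skel.timestamps.copy(), joints=joints,
                            rate_hz=skel.rate_hz)


def filter_imu(rec: ImuRecording, spec: FilterSpec) -> ImuRecording:
    """Filter all six IMU channels."""
    accel = np.column_stack([butterworth_lowpass(rec.accel[:, c], spec, rec.rate_hz)
                             for c in range(3)])
    gyro = np.column_stack([butterworth_lowpass(rec.gyro[:, c], spec, rec.rate_hz)
                            for c in range(3)])
    return ImuRecording(site=rec.site, timestamps=rec.timestamps.copy(),
                        accel=accel, gyro=gyro, rate_hz=rec.rate_hz)


def trim_nonwalking(belt: TreadmillLog, speed_threshold: float = 0.2,
                    debounce_s: float = 2.0) -> tuple[float, float]:
    """Locate the walking segment: the longest run with belt speed above
    threshold, sustained for at least ``debounce_s``.

    Returns (t_start, t_end) of the walking segment.
    """
    above = belt.speed > speed_threshold
    if not above.any():
        raise DataError("no walking detected: belt never exceeds threshold")
    idx = np.flatnonzero(above)
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    best = None
    for run in runs:
        t0, t1 = belt.timestamps[run[0]], belt.timestamps[run[-1]]
        if t1 - t0 < debounce_s:
            continue
        if best is None or (t1 - t0) > (best[1] - best[0]):
            best = (t0, t1)
    if best is None:
        raise DataError("no walking detected: no sustained run above threshold")
    return best


def select_window(segment: tuple[float, float], length_s: float = 120.0) -> AnalysisWindow:
    """Last ``length_s`` seconds of the walking segment, clipped to its start."""
    t0, t1 = segment
    start = t1 - length_s
    if start < t0:
        log.warning("walking segment (%.1f s) shorter than requested window "
                    "(%.1f s); clipping", t1 - t0, length_s)
        start = t0
    return AnalysisWindow(t_start=start, t_end=t1)
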