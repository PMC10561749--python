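"""Shared domain types for dual-modality treadmill gait analysis.

All kinematic quantities live in a canonical body-axes frame:
``X`` = subject's right, ``Y`` = up, ``Z`` = anterior (walking direction).
Units are SI throughout (metres, seconds, m/s², rad/s) unless a field name
says otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# errors

class GaitError(Exception):
    """Base class for all package errors."""


class FormatError(GaitError):
    """A file does not conform to the expected dialect (missing columns,
    unknown unit strings, wrong channel count)."""


class DataError(GaitError):
    """A file parses but its content is physically invalid (non-monotone
    timestamps, negative belt speed, interval outside a log)."""


class ConfigError(GaitError):
    """Configuration values are inconsistent (cutoff above Nyquist,
    unresolvable event spacing, missing axis mapping)."""


class InsufficientGaitCycles(DataError):
    """Fewer than two gait cycles are detectable in the analysis window."""


# ---------------------------------------------------------------------------
# constants

LEFT = "LEFT"
RIGHT = "RIGHT"
SIDES = (LEFT, RIGHT)

IC = "IC"
TO = "TO"

KINEMATIC = "KINEMATIC"
IMU = "IMU"
SOURCES = (KINEMATIC, IMU)

FOOT_L = "FOOT_L"
FOOT_R = "FOOT_R"
WRIST_L = "WRIST_L"
WRIST_R = "WRIST_R"
LUMBAR = "LUMBAR"
STERNUM = "STERNUM"
IMU_SITES = (FOOT_L, FOOT_R, WRIST_L, WRIST_R, LUMBAR, STERNUM)

#: gravitational acceleration used throughout, m/s²
GRAVITY = 9.81

#: joints every analysis needs; readers refuse files without them
REQUIRED_JOINTS = ("PELVIS", "ANKLE_L", "ANKLE_R")

#: full joint vocabulary the simulator emits (subset of the 32-joint set)
KNOWN_JOINTS = (
    "PELVIS",
    "SHOULDER_L", "SHOULDER_R",
    "WRIST_L", "WRIST_R",
    "ANKLE_L", "ANKLE_R",
    "TOE_L", "TOE_R",
)


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# streams

@dataclass
class SkeletonSequence:
    """Time-stamped 3D joint positions (the depth-camera stream after pose
    estimation), in the canonical frame and metres.

    ``joints`` maps joint name -> (n, 3) array aligned with ``timestamps``.
    """

    timestamps: np.ndarray
    joints: dict[str, np.ndarray]
    rate_hz: float = 30.0

    def __post_init__(self):
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DataError("skeleton timestamps must be strictly increasing")
        n = len(self.timestamps)
        for name, arr in self.joints.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(
                    f"joint {name} has shape {arr.shape}, expected ({n}, 3)"
                )
            self.joints[name] = arr

    def __len__(self) -> int:
        return len(self.timestamps)

    def require(self, *names: str) -> None:
        missing = [j for j in names if j not in self.joints]
        if missing:
            raise FormatError(f"required joint {missing[0]} missing")

    def crop(self, t0: float, t1: float) -> "SkeletonSequence":
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return SkeletonSequence(
            timestamps=self.timestamps[m],
            joints={k: v[m] for k, v in self.joints.items()},
            rate_hz=self.rate_hz,
        )


@dataclass
class ImuRecording:
    """One sensor site's 3-axis acceleration (m/s²) and angular velocity
    (rad/s).  Axis convention matches the canonical body frame unless the
    recording was produced in a rotated sensor frame (see
    :func:`gaitagree.synthetic.imu_sensor_frame`)."""

    site: str
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    rate_hz: float = 128.0

    def __post_init__(self):
        if self.site not in IMU_SITES:
            raise ValueError(f"unknown IMU site {self.site!r}")
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.accel = _as_float_array(self.accel, "accel", 2)
        self.gyro = _as_float_array(self.gyro, "gyro", 2)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must be (n, 3) aligned with timestamps")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    def crop(self, t0: float, t1: float) -> "ImuRecording":
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return ImuRecording(self.site, self.timestamps[m], self.accel[m],
                            self.gyro[m], self.rate_hz)


@dataclass
class TreadmillLog:
    """Belt speed vs. time; the source of all belt-translation terms."""

    timestamps: np.ndarray
    speed: np.ndarray
    rate_hz: float = 64.0

    def __post_init__(self):
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.speed = _as_float_array(self.speed, "speed", 1)
        if len(self.timestamps) != len(self.speed):
            raise ValueError("timestamps and speed must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DataError("treadmill timestamps must be strictly increasing")
        if np.any(self.speed < 0):
            raise DataError("belt speed must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    def speed_at(self, t) -> np.ndarray:
        """Belt speed linearly interpolated at time(s) ``t``."""
        return np.interp(t, self.timestamps, self.speed)


# ---------------------------------------------------------------------------
# events & metadata

@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single timestamped gait event (initial contact or toe-off)."""

    time: float
    side: str
    kind: str  # IC or TO
    source: str  # KINEMATIC or IMU

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.kind not in (IC, TO):
            raise ValueError("kind must be IC or TO")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")


@dataclass
class ParticipantMeta:
    """Per-participant metadata used by the analysis."""

    id: str
    preferred_speed: float  # m/s
    leg_length: float  # m, pendulum length for the stability model
    group: str = "NON_FALLER"  # FALLER / NON_FALLER

    def __post_init__(self):
        if self.preferred_speed <= 0:
            raise ValueError("preferred_speed must be positive")
        if self.leg_length <= 0:
            raise ValueError("leg_length must be positive")
        if self.group not in ("FALLER", "NON_FALLER"):
            raise ValueError("group must be FALLER or NON_FALLER")


@dataclass
class Stride:
    """One ipsilateral IC-to-IC interval with the events it contains.

    Optional events are ``None`` when not detected; parameters that need
    them are then left absent (NaN in tables), never zero.
    """

    side: str
    t_ic: float
    t_ic_next: float
    t_to: Optional[float] = None
    t_contra_ic: Optional[float] = None
    t_contra_to: Optional[float] = None

    @property
    def stride_time(self) -> float:
        return self.t_ic_next - self.t_ic


#: column order of the per-stride table
STRIDE_COLUMNS = [
    "side", "ic_time", "stride_time", "stride_length",
    "single_support", "double_support", "step_width",
    "mos_ml", "mos_ap", "arm_swing", "source",
]

#: parameters averaged into a summary row
SUMMARY_PARAMS = [
    "stride_time", "stride_length", "single_support", "double_support",
    "step_width", "mos_ml", "mos_ap", "cadence",
    "arm_swing_left", "arm_swing_right",
]
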