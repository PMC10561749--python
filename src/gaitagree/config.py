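"""Analysis configuration with documented defaults, loadable from YAML."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .types import ConfigError


@dataclass
class FilterSpec:
    """Low-pass Butterworth filter settings.

    ``order`` is the per-pass design order; with ``zero_phase`` the filter is
    applied forward and backward (zero group delay, squared magnitude).
    """

    order: int
    cutoff_hz: float
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be positive")


@dataclass
class AxisMap:
    """Signed mapping from source-frame axes to the canonical body frame.

    Each entry names the source axis (with optional sign) that supplies a
    canonical axis, e.g. depth-camera ``X-right / Y-down / Z-away`` maps to
    canonical via ``x='+x', y='-y', z='-z'`` (anterior = towards the camera,
    which faces the subject).
    """

    x: str = "+x"
    y: str = "+y"
    z: str = "+z"

    def matrix(self):
        import numpy as np

        cols = []
        for spec in (self.x, self.y, self.z):
            s = spec.strip().lower()
            sign = 1.0
            if s[0] in "+-":
                sign = -1.0 if s[0] == "-" else 1.0
                s = s[1:]
            if s not in ("x", "y", "z"):
                raise ConfigError(f"bad axis spec {spec!r}")
            col = np.zeros(3)
            col["xyz".index(s)] = sign
            cols.append(col)
        m = np.column_stack(cols).T  # canonical = m @ source
        if abs(abs(float(np.linalg.det(m))) - 1.0) > 1e-12:
            raise ConfigError("axis map must use each source axis exactly once")
        return m

    def apply(self, arr):
        """Map an (n, 3) source-frame array into the canonical frame."""
        return arr @ self.matrix().T


#: default depth-camera frame: X right, Y down, Z away from the camera.
#: The camera faces the subject, so canonical anterior = -Z, up = -Y.
DEPTH_CAMERA_AXES = AxisMap(x="+x", y="-y", z="-z")

#: identity map for data already in canonical body axes
IDENTITY_AXES = AxisMap()


@dataclass
class AnalysisConfig:
    """Bundle of all tunables of the pipeline."""

    filter_imu: FilterSpec = field(default_factory=lambda: FilterSpec(order=4, cutoff_hz=10.0))
    filter_skeleton: FilterSpec = field(default_factory=lambda: FilterSpec(order=1, cutoff_hz=6.0))
    window_length_s: float = 120.0
    trim_speed_threshold: float = 0.2  # m/s
    trim_debounce_s: float = 2.0
    peak_prominence_frac: float = 0.3  # fraction of median swing-peak height
    peak_spacing_frac: float = 0.5  # fraction of median stride time
    loa_multiplier: float = 1.96
    max_gap_frames: int = 3  # skeleton dropout interpolation limit
    imu_ml_axis: int = 0  # gyro column of the mediolateral axis
    imu_ml_sign: float = 1.0
    imu_ap_axis: int = 2  # accel column of the anteroposterior axis
    dedrift_imu_velocity: bool = True
    belt_interval_full_stride: bool = False  # alternative belt-term reading
    event_landmark: str = "ANKLE"  # ANKLE / TOE driving the position detector

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "filters":
                if "imu" in val:
                    cfg.filter_imu = FilterSpec(
                        order=val["imu"].get("order", 4),
                        cutoff_hz=val["imu"].get("cutoff", 10.0),
                        zero_phase=val["imu"].get("zero_phase", True),
                    )
                if "skeleton" in val:
                    cfg.filter_skeleton = FilterSpec(
                        order=val["skeleton"].get("order", 1),
                        cutoff_hz=val["skeleton"].get("cutoff", 6.0),
                        zero_phase=val["skeleton"].get("zero_phase", True),
                    )
            elif key == "window":
                cfg.window_length_s = val.get("length_s", cfg.window_length_s)
            elif key == "trim":
                cfg.trim_speed_threshold = val.get("speed_threshold", cfg.trim_speed_threshold)
                cfg.trim_debounce_s = val.get("debounce_s", cfg.trim_debounce_s)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
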