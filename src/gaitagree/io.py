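"""Readers and writers for the three device streams and result tables.

File dialects are UTF-8 CSV with a single header row and "." decimals
(JSON alternative for skeletons).  Readers refuse files that would silently
change units: IMU files must declare their units in a leading comment line,
and belt logs must be in m/s.
"""
from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import AxisMap, IDENTITY_AXES
from .types import (DataError, FormatError, GaitEvent, ImuRecording,
                    REQUIRED_JOINTS, SkeletonSequence, TreadmillLog)

log = logging.getLogger("gaitagree")

_ACCEL_UNITS = {"m/s2": 1.0, "m/s^2": 1.0, "g": 9.81}
_GYRO_UNITS = {"rad/s": 1.0, "deg/s": math.pi / 180.0}


# ---------------------------------------------------------------------------
# skeleton

def _interpolate_gaps(ts: np.ndarray, arr: np.ndarray, max_gap: int) -> tuple[np.ndarray, int]:
    """Fill NaN runs of length <= max_gap by linear interpolation in time.

    Returns the filled array and the number of interpolated frames.  Longer
    runs are left NaN for the caller to handle.
    """
    out = arr.copy()
    filled = 0
    bad = np.isnan(arr).any(axis=1)
    if not bad.any():
        return out, 0
    # contiguous runs of bad frames
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    for run in splits:
        if len(run) == 0 or len(run) > max_gap:
            continue
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(arr):
            continue  # edge gaps cannot be interpolated
        for c in range(3):
            out[run, c] = np.interp(ts[run], [ts[lo], ts[hi]], [arr[lo, c], arr[hi, c]])
        filled += len(run)
    return out, filled


def read_skeleton(path, axes: AxisMap = IDENTITY_AXES,
                  required: Iterable[str] = REQUIRED_JOINTS,
                  max_gap_frames: int = 3) -> SkeletonSequence:
    """Read a skeleton stream (long/wide CSV or JSON) into the canonical frame.

    Long CSV columns: ``time, joint, x, y, z``.  Wide CSV columns: ``time``
    plus ``<JOINT>_x/_y/_z`` triplets.  JSON: ``{"rate_hz": .., "timestamps":
    [..], "joints": {"NAME": [[x,y,z], ..]}}``.  Coordinates are metres in the
    source frame declared by ``axes``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        ts = np.asarray(raw["timestamps"], dtype=float)
        joints = {k: np.asarray(v, dtype=float) for k, v in raw["joints"].items()}
        rate = float(raw.get("rate_hz", 30.0))
    else:
        df = pd.read_csv(path)
        if "joint" in df.columns:  # long format
            ts = df["time"].unique().astype(float)  # file order
            if len(ts) > 1 and not np.all(np.diff(ts) > 0):
                raise DataError("skeleton timestamps must be strictly increasing")
            joints = {}
            for name, sub in df.groupby("joint"):
                sub = sub.set_index("time").reindex(ts)
                joints[str(name)] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        else:  # wide format
            if "time" not in df.columns:
                raise FormatError("skeleton CSV needs a 'time' column")
            ts = df["time"].to_numpy(dtype=float)
            names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
            joints = {}
            for name in names:
                cols = [f"{name}_x", f"{name}_y", f"{name}_z"]
                if not all(c in df.columns for c in cols):
                    raise FormatError(f"joint {name} has incomplete x/y/z columns")
                joints[name] = df[cols].to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 30.0

    for j in required:
        if j not in joints:
            raise FormatError(f"required joint {j} missing")
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise DataError("skeleton timestamps must be strictly increasing")

    n_filled = 0
    for name in list(joints):
        joints[name], k = _interpolate_gaps(ts, joints[name], max_gap_frames)
        n_filled += k
    if n_filled:
        log.info("skeleton: interpolated %d dropped frames", n_filled)

    # drop frames still NaN in any required joint (long dropouts)
    bad = np.zeros(len(ts), dtype=bool)
    for j in required:
        bad |= np.isnan(joints[j]).any(axis=1)
    if bad.any():
        log.info("skeleton: dropped %d frames with unrecoverable gaps", int(bad.sum()))
        ts = ts[~bad]
        joints = {k: v[~bad] for k, v in joints.items()}
    if any(np.isnan(v).any() for v in joints.values()):
        # non-required joints may retain gaps only where the whole frame survived;
        # forward-fill is wrong for kinematics, so keep NaN out by dropping joints
        joints = {k: v for k, v in joints.items() if not np.isnan(v).any()}

    joints = {k: axes.apply(v) for k, v in joints.items()}
    return SkeletonSequence(timestamps=ts, joints=joints, rate_hz=rate)


def write_skeleton(skel: SkeletonSequence, path) -> None:
    """Write a canonical-frame skeleton stream as JSON (lossless dialect)."""
    path = Path(path)
    payload = {
        "rate_hz": skel.rate_hz,
        "timestamps": skel.timestamps.tolist(),
        "joints": {k: v.tolist() for k, v in skel.joints.items()},
    }
    path.write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# IMU

def read_imu(path, site: str) -> ImuRecording:
    """Read one IMU site's CSV.

    First line must be a unit declaration comment, e.g.::

        # units: accel=m/s2 gyro=rad/s

    followed by a header ``time,ax,ay,az,gx,gy,gz``.  Accelerations may be
    declared in ``g``, angular velocity in ``deg/s``; both are converted to
    SI on read (and the conversion logged).
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "units:" not in first:
            raise FormatError("IMU file must declare units in a leading '# units:' line")
        decl = first.split("units:", 1)[1]
        units = {}
        for tok in decl.replace(",", " ").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                units[k.strip()] = v.strip()
        df = pd.read_csv(fh)
    if "accel" not in units or "gyro" not in units:
        raise FormatError("unit declaration must name both accel and gyro")
    if units["accel"] not in _ACCEL_UNITS:
        raise FormatError(f"unknown accel unit {units['accel']!r}")
    if units["gyro"] not in _GYRO_UNITS:
        raise FormatError(f"unknown gyro unit {units['gyro']!r}")
    chan = [c for c in df.columns if c != "time"]
    if len(chan) != 6:
        raise FormatError(f"IMU file must have 6 channels, found {len(chan)}")
    for c in ("ax", "ay", "az", "gx", "gy", "gz"):
        if c not in df.columns:
            raise FormatError(f"IMU channel {c} missing")
    ka, kg = _ACCEL_UNITS[units["accel"]], _GYRO_UNITS[units["gyro"]]
    if ka != 1.0 or kg != 1.0:
        log.info("imu %s: converted accel×%g gyro×%g to SI", site, ka, kg)
    ts = df["time"].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float) * ka
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * kg
    rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 128.0
    return ImuRecording(site=site, timestamps=ts, accel=accel, gyro=gyro, rate_hz=rate)


def write_imu(rec: ImuRecording, path) -> None:
    """Write an IMU recording in SI units with an explicit unit declaration."""
    path = Path(path)
    df = pd.DataFrame({
        "time": rec.timestamps,
        "ax": rec.accel[:, 0], "ay": rec.accel[:, 1], "az": rec.accel[:, 2],
        "gx": rec.gyro[:, 0], "gy": rec.gyro[:, 1], "gz": rec.gyro[:, 2],
    })
    with path.open("w") as fh:
        fh.write("# units: accel=m/s2 gyro=rad/s\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# treadmill + results

def read_treadmill(path) -> TreadmillLog:
    """Read a belt-speed log CSV with columns ``time, speed`` (s, m/s)."""
    df = pd.read_csv(path)
    for c in ("time", "speed"):
        if c not in df.columns:
            raise FormatError(f"belt log column {c} missing")
    ts = df["time"].to_numpy(dtype=float)
    speed = df["speed"].to_numpy(dtype=float)
    if np.any(speed < 0):
        raise DataError("belt speed must be non-negative")
    rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 64.0
    return TreadmillLog(timestamps=ts, speed=speed, rate_hz=rate)


def write_treadmill(belt: TreadmillLog, path) -> None:
    pd.DataFrame({"time": belt.timestamps, "speed": belt.speed}).to_csv(path, index=False)


def write_events(events: list[GaitEvent], path) -> None:
    pd.DataFrame(
        [{"time": e.time, "side": e.side, "kind": e.kind, "source": e.source}
         for e in events]
    ).to_csv(path, index=False)


def read_events(path) -> list[GaitEvent]:
    df = pd.read_csv(path)
    return [GaitEvent(float(r.time), str(r.side), str(r.kind), str(r.source))
            for r in df.itertuples()]


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each named table as ``<name>.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        log.info("wrote %s (%d rows)", p, len(df))
        written.append(p)
    return written
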