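"""End-to-end per-trial analysis: streams in, per-stride and summary tables out."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import events as ev
from . import parameters as par
from .config import AnalysisConfig
from .preprocessing import (filter_imu, filter_skeleton, select_window,
                            trim_nonwalking)
from .types import (IMU, KINEMATIC, LEFT, RIGHT, FOOT_L, FOOT_R, WRIST_L,
                    WRIST_R, ImuRecording, ParticipantMeta, SkeletonSequence,
                    TreadmillLog)

log = logging.getLogger("gaitagree")


def analyze_trial(skel: SkeletonSequence, imus: dict[str, ImuRecording],
                  belt: TreadmillLog, meta: ParticipantMeta,
                  config: AnalysisConfig | None = None) -> dict:
    """Run the full dual-modality analysis of one treadmill trial.

    Returns a dict with the analysis window, both event lists, both
    per-stride tables and both window-summary rows.
    """
    cfg = config or AnalysisConfig()
    segment = trim_nonwalking(belt, cfg.trim_speed_threshold, cfg.trim_debounce_s)
    window = select_window(segment, cfg.window_length_s)
    log.info("walking segment %.1f-%.1f s; window %.1f-%.1f s",
             *segment, window.t_start, window.t_end)

    skel_f = filter_skeleton(skel, cfg.filter_skeleton)
    imus_f = {site: filter_imu(rec, cfg.filter_imu) for site, rec in imus.items()}

    # --- kinematic modality ---------------------------------------------
    kin_events = ev.detect_events_kinematic(skel_f, window,
                                            landmark=cfg.event_landmark)
    kin_strides = ev.pair_strides(kin_events)
    single, double = par.support_times(kin_strides)
    mos = par.MosParams(l=meta.leg_length)
    mos_ml, mos_ap = par.margin_of_stability(skel_f, kin_strides, mos)
    arm_by_side = {
        side: par.arm_swing_kinematic(skel_f, window, side)
        for side in (LEFT, RIGHT)
        if f"WRIST_{side[0]}" in skel_f.joints and f"SHOULDER_{side[0]}" in skel_f.joints
    }
    kin_table = par.stride_table(
        kin_strides, KINEMATIC,
        stride_length=par.stride_length_kinematic(skel_f, kin_strides, belt),
        single_support=single, double_support=double,
        step_width=par.step_width(skel_f, kin_strides),
        mos_ml=mos_ml, mos_ap=mos_ap,
    )
    kin_summary = par.summarize_window(
        kin_table, window, participant=meta.id,
        extra=_arm_extra(arm_by_side) | {
            "cadence": par.cadence(kin_events, window),
            "group": meta.group,
        })

    # --- inertial modality ----------------------------------------------
    imu_events = []
    for site in (FOOT_L, FOOT_R):
        imu_events += ev.detect_events_imu(
            imus_f[site], window, ml_axis=cfg.imu_ml_axis,
            ml_sign=cfg.imu_ml_sign,
            prominence_frac=cfg.peak_prominence_frac,
            spacing_frac=cfg.peak_spacing_frac)
    imu_events.sort()
    imu_strides = ev.pair_strides(imu_events)
    single_i, double_i = par.support_times(imu_strides)
    # stride length integrates the unfiltered acceleration (see parameters)
    sl = np.full(len(imu_strides), np.nan)
    for site in (FOOT_L, FOOT_R):
        vals = par.stride_length_imu(
            imus[site], imu_strides, belt, ap_axis=cfg.imu_ap_axis,
            dedrift=cfg.dedrift_imu_velocity,
            belt_interval_full_stride=cfg.belt_interval_full_stride)
        sl = np.where(np.isnan(vals), sl, vals)
    arm_imu = {side: par.arm_swing_imu(imus_f[site], window)
               for side, site in ((LEFT, WRIST_L), (RIGHT, WRIST_R))
               if site in imus_f}
    imu_table = par.stride_table(
        imu_strides, IMU, stride_length=sl,
        single_support=single_i, double_support=double_i,
    )
    imu_summary = par.summarize_window(
        imu_table, window, participant=meta.id,
        extra=_arm_extra(arm_imu) | {
            "cadence": par.cadence(imu_events, window),
            "group": meta.group,
        })

    return {
        "window": window,
        "events": {KINEMATIC: kin_events, IMU: imu_events},
        "stride_tables": {KINEMATIC: kin_table, IMU: imu_table},
        "summaries": pd.DataFrame([kin_summary, imu_summary]),
    }


def _arm_extra(arm_by_side: dict[str, np.ndarray]) -> dict:
    out = {}
    for side, amps in arm_by_side.items():
        if len(amps):
            out[f"arm_swing_{side.lower()}"] = float(np.mean(amps))
    return out
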