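"""Shared fixtures: simulated trials and event-matching helpers."""
from __future__ import annotations

import numpy as np
import pytest

import gaitagree as g
from gaitagree.preprocessing import AnalysisWindow


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, jitter-free steady trial (40 s of walking)."""
    return g.simulate_trial(g.GaitProfile(), duration_walk=40.0, seed=11)


@pytest.fixture(scope="session")
def noisy_trial():
    """Trial at the realistic noise levels used throughout the suite."""
    profile = g.GaitProfile(stride_cv=0.02, noise_skeleton_m=0.003,
                            noise_wrist_m=0.025, noise_accel=0.05,
                            noise_gyro=0.01)
    return g.simulate_trial(profile, duration_walk=40.0, seed=12)


def steady_window(trial, margin: float = 8.0) -> AnalysisWindow:
    """Interior window of the walking phase, clear of belt ramps."""
    t0, t1 = trial.truth.walk_interval
    return AnalysisWindow(t0 + margin, t1 - margin)


def match_events(detected: np.ndarray, truth: np.ndarray, tol: float):
    """Greedy nearest matching of detected to true event times.

    Returns (per-true errors for matched events, sensitivity, precision)
    where a match requires |error| <= tol.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    errors, hits = [], 0
    used = np.zeros(len(detected), dtype=bool)
    for t in truth:
        if len(detected) == 0:
            break
        i = int(np.argmin(np.abs(detected - t)))
        err = detected[i] - t
        if abs(err) <= tol and not used[i]:
            used[i] = True
            hits += 1
            errors.append(err)
    sensitivity = hits / len(truth) if len(truth) else np.nan
    precision = used.sum() / len(detected) if len(detected) else np.nan
    return np.array(errors), sensitivity, precision


@pytest.fixture
def event_matcher():
    return match_events
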