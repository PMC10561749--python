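"""Paired method-agreement statistics across participants.

For each gait parameter measured by both modalities: Shapiro–Wilk
normality per method, a two-sided paired t-test, convergent-validity
correlation (Pearson when both margins are normal, Spearman otherwise)
and Bland–Altman agreement with limits of agreement (LoA).

The difference direction is fixed as IMU − kinematic throughout, and the
LoA multiplier defaults to 1.96 (mean difference ± 1.96 SD).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import DataError, IMU, KINEMATIC, SUMMARY_PARAMS

log = logging.getLogger("gaitagree")


@dataclass
class AgreementReport:
    """Per-parameter paired comparison of the two measurement systems."""

    parameter: str
    n: int
    normality_p_a: float
    normality_p_b: float
    t_stat: float
    t_p: float
    exact_offset: bool
    corr_method: str
    corr_r: float
    corr_p: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float
    n_outside_loa: int
    pct_outside_loa: float


def normality_test(values) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value; requires 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise DataError(f"Shapiro-Wilk needs 3..5000 samples, got {len(values)}")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def paired_t(values_a, values_b) -> tuple[float, float, float, bool]:
    """Two-sided paired t-test on a − b.

    Returns (t, p, mean difference, exact_offset flag).  Zero-variance
    differences are degenerate for the t statistic: identical vectors give
    (0, 1); a constant non-zero offset is flagged ``exact_offset`` with
    p = 0 (the difference is certain).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise DataError("paired t-test needs two equal-length vectors, n >= 2")
    d = a - b
    mean_diff = float(np.mean(d))
    if float(np.std(d, ddof=1)) == 0.0:
        if mean_diff == 0.0:
            return 0.0, 1.0, 0.0, False
        return float(np.inf if mean_diff > 0 else -np.inf), 0.0, mean_diff, True
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), mean_diff, False


def correlate(values_a, values_b, normal: bool) -> tuple[str, float, float]:
    """Convergent-validity correlation.

    Pearson when both margins are normal (``normal`` True), Spearman's
    rank correlation otherwise; the choice is returned with the
    coefficient.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise DataError("correlation needs two equal-length vectors, n >= 3")
    if normal:
        res = stats.pearsonr(a, b)
        return "Pearson", float(res.statistic), float(res.pvalue)
    res = stats.spearmanr(a, b)
    return "Spearman", float(res.statistic), float(res.pvalue)


def bland_altman(values_a, values_b, multiplier: float = 1.96) -> dict:
    """Bland–Altman agreement of paired measurements (diffs = a − b).

    Returns mean difference, sample SD (n−1 denominator), limits of
    agreement mean ± multiplier × SD, and the count/percentage of pairs
    strictly outside the limits.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise DataError("Bland-Altman needs two equal-length vectors, n >= 2")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_low = mean_diff - multiplier * sd_diff
    loa_high = mean_diff + multiplier * sd_diff
    outside = int(np.sum((d < loa_low) | (d > loa_high)))
    return {
        "n": len(d),
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": loa_low,
        "loa_high": loa_high,
        "loa_multiplier": multiplier,
        "n_outside_loa": outside,
        "pct_outside_loa": 100.0 * outside / len(d),
        "means": (a + b) / 2.0,
        "diffs": d,
    }


def full_report(summaries: pd.DataFrame, parameters: list[str] | None = None,
                multiplier: float = 1.96, alpha: float = 0.05
                ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-parameter agreement across participants.

    ``summaries`` holds one row per participant × source with window-mean
    parameters.  Participants missing either modality for a parameter are
    dropped (count logged).  Returns the report table plus per-parameter
    scatter data (participant, mean, diff, and both raw values) for
    Bland–Altman and correlation plots.
    """
    if parameters is None:
        parameters = [p for p in SUMMARY_PARAMS if p in summaries.columns]
    wide = summaries.pivot_table(index="participant", columns="source",
                                 values=parameters, aggfunc="first")
    rows = []
    scatter: dict[str, pd.DataFrame] = {}
    for param in parameters:
        if (param, IMU) not in wide.columns or (param, KINEMATIC) not in wide.columns:
            continue
        sub = wide[param][[IMU, KINEMATIC]].dropna()
        dropped = len(wide) - len(sub)
        if dropped:
            log.info("%s: dropped %d participants missing a modality", param, dropped)
        if len(sub) < 3:
            raise DataError(f"{param}: fewer than 3 complete participant pairs")
        a = sub[IMU].to_numpy()       # difference direction: IMU − kinematic
        b = sub[KINEMATIC].to_numpy()
        _, p_a = normality_test(a)
        _, p_b = normality_test(b)
        t, p_t, _, exact = paired_t(a, b)
        method, r, p_r = correlate(a, b, normal=(p_a > alpha and p_b > alpha))
        ba = bland_altman(a, b, multiplier=multiplier)
        rows.append(AgreementReport(
            parameter=param, n=len(sub),
            normality_p_a=p_a, normality_p_b=p_b,
            t_stat=t, t_p=p_t, exact_offset=exact,
            corr_method=method, corr_r=r, corr_p=p_r,
            mean_diff=ba["mean_diff"], sd_diff=ba["sd_diff"],
            loa_low=ba["loa_low"], loa_high=ba["loa_high"],
            loa_multiplier=multiplier,
            n_outside_loa=ba["n_outside_loa"],
            pct_outside_loa=ba["pct_outside_loa"],
        ))
        scatter[param] = pd.DataFrame({
            "participant": sub.index,
            "imu": a, "kinematic": b,
            "mean": ba["means"], "diff": ba["diffs"],
        })
    report = pd.DataFrame([asdict(r) for r in rows])
    return report, scatter
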