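"""Error statistics and standard evaluation protocols for delineation.

Implements the signed time-error (TE) and duration-error (DE) statistics
with sample standard deviation (n-1 denominator), plus the three outlier
policies used when reporting interval-measurement accuracy:

* ``trimmed_stats`` -- keep values with |v| <= the 95th percentile of |v|,
  the trimming used when calibrating measurement thresholds;
* ``cap_outliers_3sd`` -- clamp values into mean +/- 3*std (single pass),
  the policy for clinical-database error reports;
* ``drop_k_protocol`` -- remove the k largest deviations from the mean
  before summarizing, with k=8 for the 100-record standard interval test
  and k=2 for the 10-record noise-immunity test.

The standard interval tolerances (P +/-10/15, PQ +/-10/10, QRS +/-10/10,
QT +/-25/30 ms for mean/std) are checked by ``tolerance_check``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .beat_model import FS, DurationSet, FiducialSet

__all__ = ["ErrorStats", "DetectionCounts", "ToleranceTable",
           "time_errors", "duration_errors", "noise_duration_errors",
           "trimmed_stats", "cap_outliers_3sd", "drop_k_protocol",
           "raw_stats", "tolerance_check", "detection_rates",
           "FIDUCIAL_NAMES", "INTERVAL_NAMES"]

FIDUCIAL_NAMES = ("p_onset", "p_offset", "qrs_onset", "qrs_offset", "t_offset")
INTERVAL_NAMES = ("p_dur", "pq_int", "qrs_dur", "qt_int")


@dataclass(frozen=True)
class ErrorStats:
    mean: float
    std: float
    n_total: int
    n_used: int
    policy: str = "raw"

    def __post_init__(self) -> None:
        if self.n_used > self.n_total:
            raise ValueError("n_used cannot exceed n_total")


@dataclass(frozen=True)
class DetectionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ToleranceTable:
    """Per-interval (mean, std) tolerances in ms."""

    p_dur: tuple[float, float] = (10.0, 15.0)
    pq_int: tuple[float, float] = (10.0, 10.0)
    qrs_dur: tuple[float, float] = (10.0, 10.0)
    qt_int: tuple[float, float] = (25.0, 30.0)


def _mean_std(v: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(v))
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return mean, std


def raw_stats(values) -> ErrorStats:
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty value list")
    mean, std = _mean_std(v)
    return ErrorStats(mean, std, v.size, v.size, "raw")


def trimmed_stats(values, q: float = 0.95) -> ErrorStats:
    """Mean/std of the values with |v| <= the q-quantile of |v|.

    The quantile is linearly interpolated; with ``q=1`` this equals the
    raw statistics.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty value list")
    cut = np.quantile(np.abs(v), q)
    kept = v[np.abs(v) <= cut]
    mean, std = _mean_std(kept)
    return ErrorStats(mean, std, v.size, kept.size, "trim95")


def cap_outliers_3sd(values) -> np.ndarray:
    """Clamp values into [mean-3*std, mean+3*std] (single pass).

    Mean and std are computed once on the raw values; the band is not
    recomputed after clamping.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty value list")
    mean, std = _mean_std(v)
    return np.clip(v, mean - 3.0 * std, mean + 3.0 * std)


def drop_k_protocol(values, k: int) -> ErrorStats:
    """Drop the k largest deviations from the (raw) mean, then summarize.

    The mean used for deviation ranking is computed once; ties are broken
    by removing the later index.  ``k=8`` for the 100-record standard
    interval test, ``k=2`` for the 10-record noise test.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size <= k:
        raise ValueError(f"need more than k={k} values, got {v.size}")
    dev = np.abs(v - np.mean(v))
    drop = sorted(range(v.size), key=lambda i: (dev[i], i), reverse=True)[:k]
    keep = np.delete(v, drop)
    mean, std = _mean_std(keep)
    return ErrorStats(mean, std, v.size, keep.size, "drop_k")


def time_errors(measured: Sequence[Optional[FiducialSet]],
                reference: Sequence[FiducialSet],
                fs: float = FS):
    """Signed per-fiducial time errors (ms) and P-detection counts.

    Lists are paired beat by beat; a ``None`` measurement (delineation
    failure) is excluded from every error list.  P-onset/P-offset errors
    are computed exclusively over true-positive P-wave detections; a beat
    whose P-wave exists in only one source contributes to the detection
    counts but to no P error list.
    """
    if len(measured) != len(reference):
        raise ValueError("measured and reference lists differ in length")
    ms = 1000.0 / fs
    errors: dict[str, list[float]] = {name: [] for name in FIDUCIAL_NAMES}
    tp = fn = tn = fp = 0
    for meas, ref in zip(measured, reference):
        if meas is None:
            continue
        if ref.p_present and meas.p_present:
            tp += 1
            errors["p_onset"].append((meas.p_onset - ref.p_onset) * ms)
            errors["p_offset"].append((meas.p_offset - ref.p_offset) * ms)
        elif ref.p_present:
            fn += 1
        elif meas.p_present:
            fp += 1
        else:
            tn += 1
        for name in ("qrs_onset", "qrs_offset", "t_offset"):
            errors[name].append(
                (getattr(meas, name) - getattr(ref, name)) * ms)
    return errors, DetectionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def duration_errors(measured: Sequence[Optional[DurationSet]],
                    reference: Sequence[DurationSet]):
    """Signed per-interval duration errors (ms), measured minus reference."""
    if len(measured) != len(reference):
        raise ValueError("measured and reference lists differ in length")
    errors: dict[str, list[float]] = {name: [] for name in INTERVAL_NAMES}
    for meas, ref in zip(measured, reference):
        if meas is None:
            continue
        for name in INTERVAL_NAMES:
            m, r = getattr(meas, name), getattr(ref, name)
            if m is None or r is None:
                continue
            errors[name].append(m - r)
    return errors


def noise_duration_errors(clean: Sequence[Optional[DurationSet]],
                          noisy: Sequence[Optional[DurationSet]]):
    """Paired noise-immunity errors (ms): noise-free minus noisy duration.

    A positive value means the noise shortened the measured duration.
    """
    if len(clean) != len(noisy):
        raise ValueError("clean and noisy lists differ in length")
    errors: dict[str, list[float]] = {name: [] for name in INTERVAL_NAMES}
    for c, n in zip(clean, noisy):
        if c is None or n is None:
            continue
        for name in INTERVAL_NAMES:
            cv, nv = getattr(c, name), getattr(n, name)
            if cv is None or nv is None:
                continue
            errors[name].append(cv - nv)
    return errors


def tolerance_check(stats: dict, table: ToleranceTable = ToleranceTable()):
    """Compare per-interval ErrorStats against the standard tolerances.

    Passing requires |mean| <= mean tolerance and std <= std tolerance;
    the overall verdict requires every provided interval to pass.
    """
    verdict: dict[str, bool] = {}
    for name, st in stats.items():
        tol_mean, tol_std = getattr(table, name)
        verdict[name] = abs(st.mean) <= tol_mean and st.std <= tol_std
    verdict["overall"] = all(verdict.values())
    return verdict


def detection_rates(counts: DetectionCounts) -> tuple[float, float]:
    """(TPR, TNR) = (TP/(TP+FN), TN/(TN+FP))."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("detection rates need both classes present")
    return (counts.tp / (counts.tp + counts.fn),
            counts.tn / (counts.tn + counts.fp))
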