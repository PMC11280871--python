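"""Threshold-based Measurement module: from probability maps to fiducials.

The network's three probability maps have soft rising and falling edges,
so each fiducial is read off by a calibrated threshold crossing: the onset
is the start of the longest run of samples at or above its onset
threshold, the offset is the end (half-open) of the longest run at or
above its offset threshold.  On binary maps with any threshold in (0, 1)
this reduces exactly to reading the mask run boundaries.  Selecting the
longest run makes the measurement robust to secondary bumps from
neighbouring beats inside the analysis window.

P-wave presence is decided first: a beat is positive when the peak of the
P map reaches the detection threshold (inclusive).  P-onset/P-offset are
measured only for detected P-waves.

Calibration ("Phase II training") adjusts each of the five thresholds
independently so the trimmed mean time error against reference
annotations is zero, exploiting that an onset moves later (TE up) and an
offset earlier (TE down) as its threshold rises; the P-detection
threshold maximizes TPR + TNR on the calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .beat_model import N_SAMPLES, FiducialSet, ValidationError
from .evalx import ErrorStats, trimmed_stats
from .nets import NetworkModel, make_input

__all__ = ["ThresholdSet", "CalibrationReport", "DelineationError",
           "Delineation", "p_detect", "detect_fiducials", "delineate_maps",
           "calibrate_thresholds", "calibrate_p_threshold"]

#: (threshold field, map channel, 'onset' | 'offset') per fiducial
_FIDUCIAL_SPEC = {
    "p_onset": ("thr_p_onset", 0, "onset"),
    "p_offset": ("thr_p_offset", 0, "offset"),
    "qrs_onset": ("thr_qrs_onset", 1, "onset"),
    "qrs_offset": ("thr_qrs_offset", 1, "offset"),
    "t_offset": ("thr_t_offset", 2, "offset"),
}

MS_PER_SAMPLE = 2.0


class DelineationError(RuntimeError):
    """No suprathreshold run on a mandatory (QRS/QT) channel."""


@dataclass(frozen=True)
class ThresholdSet:
    """The six calibrated probability thresholds, each in (0, 1)."""

    thr_p_onset: float = 0.5
    thr_p_offset: float = 0.5
    thr_qrs_onset: float = 0.5
    thr_qrs_offset: float = 0.5
    thr_t_offset: float = 0.5
    thr_p_detect: float = 0.5

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1)")

    def to_dict(self) -> dict:
        return {name: getattr(self, name)
                for name in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(**d)


@dataclass(frozen=True)
class CalibrationReport:
    """Trimmed TE statistics per fiducial at the calibrated thresholds."""

    te_stats: dict
    tpr: float
    tnr: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class Delineation:
    """Per-beat measurement outcome with failure/coercion flags."""

    fiducials: Optional[FiducialSet]
    failed: bool = False
    coerced: bool = False


def p_detect(maps: np.ndarray, thr: float) -> bool:
    """True iff the peak of the P map equals or exceeds the threshold."""
    return bool(np.max(maps[:, 0]) >= thr)


def _longest_run(channel: np.ndarray, thr: float) -> Optional[tuple[int, int]]:
    """Half-open (start, stop) of the longest run with value >= thr."""
    above = channel >= thr
    if not above.any():
        return None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8),
                                                   [0]))))
    starts, stops = edges[::2], edges[1::2]
    best = int(np.argmax(stops - starts))
    return int(starts[best]), int(stops[best])


def _measure(channel: np.ndarray, thr: float, which: str) -> Optional[int]:
    run = _longest_run(channel, thr)
    if run is None:
        return None
    return run[0] if which == "onset" else run[1]


def delineate_maps(maps: np.ndarray, thr: ThresholdSet) -> Delineation:
    """Extract a fiducial set from 512x3 probability maps.

    Returns a failed Delineation when the QRS or QT channel never reaches
    its threshold; index-ordering violations between channels are coerced
    into a valid set and flagged.
    """
    maps = np.asarray(maps)
    raw = {}
    for name in ("qrs_onset", "qrs_offset", "t_offset"):
        t_name, chan, which = _FIDUCIAL_SPEC[name]
        raw[name] = _measure(maps[:, chan], getattr(thr, t_name), which)
    if any(v is None for v in raw.values()):
        return Delineation(None, failed=True)

    coerced = False
    qrs_on = min(raw["qrs_onset"], N_SAMPLES - 1)
    qrs_off = min(max(raw["qrs_offset"], qrs_on), N_SAMPLES - 1)
    t_off = min(max(raw["t_offset"], qrs_off), N_SAMPLES - 1)
    coerced |= (qrs_on, qrs_off, t_off) != (
        raw["qrs_onset"], raw["qrs_offset"], raw["t_offset"])

    has_p = p_detect(maps, thr.thr_p_detect)
    p_on = p_off = None
    if has_p:
        p_on = _measure(maps[:, 0], thr.thr_p_onset, "onset")
        p_off = _measure(maps[:, 0], thr.thr_p_offset, "offset")
        if p_on is None or p_off is None:
            # detection fired but no run reaches the measurement thresholds
            has_p, p_on, p_off = False, None, None
            coerced = True
        else:
            new_off = min(p_off, qrs_on)
            new_on = min(p_on, new_off)
            coerced |= (new_on, new_off) != (p_on, p_off)
            p_on, p_off = new_on, new_off
    fids = FiducialSet(qrs_onset=qrs_on, qrs_offset=qrs_off, t_offset=t_off,
                       p_present=has_p, p_onset=p_on, p_offset=p_off)
    return Delineation(fids, failed=False, coerced=coerced)


def detect_fiducials(maps: np.ndarray, thr: ThresholdSet) -> FiducialSet:
    """Like :func:`delineate_maps` but raises on delineation failure."""
    result = delineate_maps(maps, thr)
    if result.failed:
        raise DelineationError("no suprathreshold run on QRS or QT channel")
    return result.fiducials


def calibrate_p_threshold(scores: Sequence[tuple[float, bool]]) -> float:
    """Operating point maximizing TPR + TNR for P-wave detection.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus the two extremes (detect-all, reject-all).  Ties
    are broken by minimal |TPR - TNR|, then by the larger threshold.
    """
    pos = np.array([s for s, label in scores if label], dtype=np.float64)
    neg = np.array([s for s, label in scores if not label], dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("calibration needs both P-present and P-absent beats")
    distinct = np.unique(np.concatenate([pos, neg]))
    candidates = [distinct[0]]
    candidates += [0.5 * (a + b) for a, b in zip(distinct[:-1], distinct[1:])]
    candidates.append(float(np.nextafter(distinct[-1], np.inf)))
    best = None
    for thr in candidates:
        tpr = float(np.mean(pos >= thr))
        tnr = float(np.mean(neg < thr))
        key = (tpr + tnr, -abs(tpr - tnr), thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return float(best[1])


def _te_at_threshold(channels: np.ndarray, refs: np.ndarray, theta: float,
                     which: str) -> np.ndarray:
    """Time errors (ms) of one fiducial over the calibration beats."""
    te = []
    for channel, ref in zip(channels, refs):
        meas = _measure(channel, theta, which)
        if meas is not None:
            te.append((meas - ref) * MS_PER_SAMPLE)
    return np.asarray(te)


def _trimmed_mean_te(channels, refs, theta, which) -> Optional[float]:
    te = _te_at_threshold(channels, refs, theta, which)
    if te.size == 0:
        return None
    return trimmed_stats(te).mean


def _calibrate_one(channels: np.ndarray, refs: np.ndarray, which: str,
                   tol_ms: float = 0.1, theta_tol: float = 1e-4):
    """Zero the trimmed mean TE of one fiducial by bisection on theta.

    Raising an onset threshold moves the onset later (TE increases);
    raising an offset threshold moves the offset earlier (TE decreases).
    If the mean TE has no sign change over (0, 1) the nearest-to-zero
    threshold on a 512-point grid is returned with a warning.
    """
    lo, hi = 1e-4, 1.0 - 1e-4
    sign = 1.0 if which == "onset" else -1.0
    f_lo = _trimmed_mean_te(channels, refs, lo, which)
    f_hi = _trimmed_mean_te(channels, refs, hi, which)

    def grid_fallback():
        grid = np.linspace(lo, hi, 512)
        means = [_trimmed_mean_te(channels, refs, g, which) for g in grid]
        finite = [(abs(m), g, m) for g, m in zip(grid, means) if m is not None]
        if not finite:
            return 0.5, None, "no measurable beats at any threshold"
        _, theta, mean = min(finite)
        return theta, mean, "no sign change of mean TE; grid argmin used"

    if f_lo is None or f_hi is None or not (sign * f_lo <= 0.0 <= sign * f_hi):
        return grid_fallback()

    # ties on |mean TE| (e.g. binary maps, where TE == 0 everywhere)
    # resolve toward the neutral threshold 0.5
    best = min((abs(f_lo), abs(lo - 0.5), lo, f_lo),
               (abs(f_hi), abs(hi - 0.5), hi, f_hi))
    while hi - lo > theta_tol:
        mid = 0.5 * (lo + hi)
        f_mid = _trimmed_mean_te(channels, refs, mid, which)
        if f_mid is None:
            return grid_fallback()
        best = min(best, (abs(f_mid), abs(mid - 0.5), mid, f_mid))
        if abs(f_mid) < tol_ms:
            break
        if sign * f_mid < 0.0:
            lo = mid
        else:
            hi = mid
    _, _, theta, mean = best
    return theta, mean, None


def calibrate_thresholds(model: NetworkModel, calib_set):
    """Calibrate all six thresholds against annotated calibration beats.

    ``calib_set`` is a list of ``(RepresentativeBeat, FiducialSet)``.
    Returns ``(ThresholdSet, CalibrationReport)``; the report carries the
    trimmed mean/std TE at the calibrated thresholds and the P-detection
    TPR/TNR at the chosen operating point.
    """
    beats = [b for b, _ in calib_set]
    refs = [f for _, f in calib_set]
    x = np.stack([make_input(b).values for b in beats])
    forward = getattr(model, "forward_batched", model.forward_batch)
    maps = forward(x)

    scores = [(float(np.max(m[:, 0])), f.p_present)
              for m, f in zip(maps, refs)]
    thr_p_detect = calibrate_p_threshold(scores)
    thr_p_detect = min(max(thr_p_detect, 1e-6), 1.0 - 1e-6)
    tp = sum(1 for (s, y) in scores if y and s >= thr_p_detect)
    fn = sum(1 for (s, y) in scores if y and s < thr_p_detect)
    tn = sum(1 for (s, y) in scores if not y and s < thr_p_detect)
    fp = sum(1 for (s, y) in scores if not y and s >= thr_p_detect)
    tpr = tp / max(tp + fn, 1)
    tnr = tn / max(tn + fp, 1)

    thresholds = {"thr_p_detect": thr_p_detect}
    te_stats: dict[str, ErrorStats] = {}
    warnings: list[str] = []
    for name, (t_name, chan, which) in _FIDUCIAL_SPEC.items():
        if name.startswith("p_"):
            # only true-positive P detections enter the P calibration
            idx = [i for i, f in enumerate(refs)
                   if f.p_present and scores[i][0] >= thr_p_detect]
        else:
            idx = list(range(len(refs)))
        channels = maps[idx][:, :, chan]
        ref_idx = np.array([getattr(refs[i], name) for i in idx])
        theta, mean, warning = _calibrate_one(channels, ref_idx, which)
        if warning:
            warnings.append(f"{name}: {warning}")
        thresholds[t_name] = theta
        te = _te_at_threshold(channels, ref_idx, theta, which)
        te_stats[name] = (trimmed_stats(te) if te.size
                          else ErrorStats(np.nan, np.nan, 0, 0, "trim95"))
    report = CalibrationReport(te_stats=te_stats, tpr=tpr, tnr=tnr,
                               warnings=tuple(warnings))
    return ThresholdSet(**thresholds), report
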