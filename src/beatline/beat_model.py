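"""Core data types for 12-lead representative-beat delineation.

A *representative beat* is a noise-reduced template heartbeat obtained by
averaging time-aligned cardiac cycles of similar morphology from a resting
12-lead ECG.  Delineation assigns five *global* fiducial points to the beat
(P-onset, P-offset, QRS-onset, QRS-offset, T-offset), common to all leads,
from which the four diagnostic intervals are derived: P-duration,
PQ-interval, QRS-duration and QT-interval.

Conventions
-----------
* Beats are 512 samples x 12 leads, sampled at 500 Hz, amplitudes in uV.
* Fiducials are 0-based integer sample indices (2 ms grid at 500 Hz).
* Wave runs are half-open ``[onset, offset)``: the onset sample belongs to
  the wave, the offset sample is the first sample after it.  This makes the
  mask <-> fiducial conversions exact inverses.
* A beat without a P-wave (atrial fibrillation, ventricular, paced, nodal
  beats...) carries ``p_present=False`` and ``p_onset``/``p_offset`` are
  ``None`` -- never 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "N_SAMPLES",
    "N_LEADS",
    "FS",
    "LEAD_NAMES",
    "RepresentativeBeat",
    "FiducialSet",
    "SegmentMasks",
    "DurationSet",
    "ValidationError",
    "DatasetError",
    "masks_from_fiducials",
    "fiducials_from_masks",
    "durations_from_fiducials",
    "read_dataset",
    "write_dataset",
]

N_SAMPLES = 512
N_LEADS = 12
FS = 500.0
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: channel order of segmentation masks / probability maps
SEGMENT_NAMES = ("P", "QRS", "QT")


class ValidationError(ValueError):
    """An object violates the domain invariants."""


class DatasetError(ValueError):
    """A dataset file is malformed; the message names record and field."""


@dataclass(frozen=True)
class RepresentativeBeat:
    """A 512x12 matrix of amplitudes (uV) at 500 Hz, fixed lead order."""

    samples: np.ndarray
    fs: float = FS
    lead_names: Sequence[str] = LEAD_NAMES
    beat_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.shape != (N_SAMPLES, N_LEADS):
            raise ValidationError(
                f"beat {self.beat_id!r}: samples must be "
                f"{N_SAMPLES}x{N_LEADS}, got {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValidationError(f"beat {self.beat_id!r}: non-finite samples")
        if self.fs != FS:
            raise ValidationError(
                f"beat {self.beat_id!r}: fs must be {FS}, got {self.fs}")
        if len(tuple(self.lead_names)) != N_LEADS:
            raise ValidationError(
                f"beat {self.beat_id!r}: expected {N_LEADS} lead names")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "lead_names", tuple(self.lead_names))


@dataclass(frozen=True)
class FiducialSet:
    """The five global fiducial sample indices plus a P-presence flag."""

    qrs_onset: int
    qrs_offset: int
    t_offset: int
    p_present: bool = True
    p_onset: Optional[int] = None
    p_offset: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("qrs_onset", "qrs_offset", "t_offset"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v < N_SAMPLES):
                raise ValidationError(f"{name}={v!r} outside [0, {N_SAMPLES})")
            object.__setattr__(self, name, int(v))
        if not self.qrs_onset <= self.qrs_offset <= self.t_offset:
            raise ValidationError(
                f"ordering violated: qrs_onset={self.qrs_onset} <= "
                f"qrs_offset={self.qrs_offset} <= t_offset={self.t_offset}")
        if self.p_present:
            for name in ("p_onset", "p_offset"):
                v = getattr(self, name)
                if v is None or not 0 <= int(v) < N_SAMPLES:
                    raise ValidationError(f"{name}={v!r} invalid with P present")
                object.__setattr__(self, name, int(v))
            if not self.p_onset <= self.p_offset <= self.qrs_onset:
                raise ValidationError(
                    f"ordering violated: p_onset={self.p_onset} <= "
                    f"p_offset={self.p_offset} <= qrs_onset={self.qrs_onset}")
        else:
            if self.p_onset is not None or self.p_offset is not None:
                raise ValidationError("P fiducials must be None when P absent")

    def shifted(self, shift: int) -> "FiducialSet":
        """Translate every defined fiducial by ``shift`` samples."""
        return FiducialSet(
            qrs_onset=self.qrs_onset + shift,
            qrs_offset=self.qrs_offset + shift,
            t_offset=self.t_offset + shift,
            p_present=self.p_present,
            p_onset=None if self.p_onset is None else self.p_onset + shift,
            p_offset=None if self.p_offset is None else self.p_offset + shift,
        )


@dataclass(frozen=True)
class SegmentMasks:
    """512x3 binary targets; channels (P-wave, QRS-complex, QT-interval).

    Each channel's ones form a single contiguous run (or are all zero, P
    only); the QRS run is contained in the QT run and both start at the
    same sample (the QT-interval runs from QRS-onset to T-offset).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (N_SAMPLES, 3):
            raise ValidationError(f"masks must be {N_SAMPLES}x3, got {v.shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("mask entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.float64))


@dataclass(frozen=True)
class DurationSet:
    """The four diagnostic durations/intervals in ms.

    ``p_dur`` and ``pq_int`` are ``None`` for beats without a P-wave.
    """

    qrs_dur: float
    qt_int: float
    p_dur: Optional[float] = None
    pq_int: Optional[float] = None


def masks_from_fiducials(f: FiducialSet) -> SegmentMasks:
    """Build the three binary training targets from a fiducial set.

    Ones cover the half-open runs [p_onset, p_offset), [qrs_onset,
    qrs_offset) and [qrs_onset, t_offset); the P channel is all zero for
    beats without a P-wave.
    """
    v = np.zeros((N_SAMPLES, 3))
    if f.p_present:
        v[f.p_onset:f.p_offset, 0] = 1.0
    v[f.qrs_onset:f.qrs_offset, 1] = 1.0
    v[f.qrs_onset:f.t_offset, 2] = 1.0
    return SegmentMasks(v)


def _single_run(channel: np.ndarray, name: str) -> Optional[tuple[int, int]]:
    """Return (start, stop) of the single half-open run of ones, or None."""
    idx = np.flatnonzero(channel)
    if idx.size == 0:
        return None
    start, stop = int(idx[0]), int(idx[-1]) + 1
    if idx.size != stop - start:
        raise ValidationError(f"{name} channel run is not contiguous")
    return start, stop


def fiducials_from_masks(m: SegmentMasks) -> FiducialSet:
    """Recover the fiducial set from binary segment masks (exact inverse)."""
    v = m.values
    p_run = _single_run(v[:, 0], "P")
    qrs_run = _single_run(v[:, 1], "QRS")
    qt_run = _single_run(v[:, 2], "QT")
    if qrs_run is None or qt_run is None:
        raise ValidationError("QRS and QT channels must contain a run")
    if qrs_run[0] != qt_run[0] or qrs_run[1] > qt_run[1]:
        raise ValidationError("QRS run must start the QT run and lie inside it")
    return FiducialSet(
        qrs_onset=qrs_run[0], qrs_offset=qrs_run[1], t_offset=qt_run[1],
        p_present=p_run is not None,
        p_onset=None if p_run is None else p_run[0],
        p_offset=None if p_run is None else p_run[1],
    )


def durations_from_fiducials(f: FiducialSet, fs: float = FS) -> DurationSet:
    """Compute P/PQ/QRS/QT durations (ms) from sample-index fiducials."""
    ms = 1000.0 / fs
    return DurationSet(
        qrs_dur=(f.qrs_offset - f.qrs_onset) * ms,
        qt_int=(f.t_offset - f.qrs_onset) * ms,
        p_dur=None if not f.p_present else (f.p_offset - f.p_onset) * ms,
        pq_int=None if not f.p_present else (f.qrs_onset - f.p_onset) * ms,
    )


# ---------------------------------------------------------------------------
# dataset I/O: one directory, one delimited text file per beat plus a JSON
# annotation sidecar.  Amplitudes round-trip bitwise (repr precision).
# ---------------------------------------------------------------------------

def _annotation_dict(f: FiducialSet) -> dict:
    return {
        "p_present": f.p_present,
        "p_onset": f.p_onset,
        "p_offset": f.p_offset,
        "qrs_onset": f.qrs_onset,
        "qrs_offset": f.qrs_offset,
        "t_offset": f.t_offset,
    }


def _fiducials_from_dict(d: dict, record: str) -> FiducialSet:
    try:
        return FiducialSet(
            qrs_onset=d["qrs_onset"], qrs_offset=d["qrs_offset"],
            t_offset=d["t_offset"], p_present=bool(d["p_present"]),
            p_onset=d.get("p_onset"), p_offset=d.get("p_offset"))
    except KeyError as e:
        raise DatasetError(f"record {record}: missing annotation field {e}")
    except ValidationError as e:
        raise DatasetError(f"record {record}: {e}")


def write_dataset(items, path) -> None:
    """Write ``[(RepresentativeBeat, FiducialSet | None), ...]`` to ``path``.

    Each beat is stored as ``<id>.csv`` (header of lead names, 512 rows of
    uV values) with an optional ``<id>.json`` annotation sidecar.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, (beat, fids) in enumerate(items):
        stem = beat.beat_id or f"beat_{i:05d}"
        lines = [",".join(beat.lead_names)]
        for row in beat.samples:
            lines.append(",".join(repr(float(x)) for x in row))
        (path / f"{stem}.csv").write_text("\n".join(lines) + "\n")
        if fids is not None:
            (path / f"{stem}.json").write_text(
                json.dumps(_annotation_dict(fids), indent=1) + "\n")


def read_dataset(path):
    """Read a dataset directory; returns ``[(beat, fiducials-or-None), ...]``."""
    path = Path(path)
    items = []
    for csv_path in sorted(path.glob("*.csv")):
        stem = csv_path.stem
        lines = csv_path.read_text().splitlines()
        if not lines:
            raise DatasetError(f"record {stem}: empty file")
        header = lines[0].split(",")
        if len(header) != N_LEADS:
            raise DatasetError(
                f"record {stem}: header has {len(header)} leads, "
                f"expected {N_LEADS}")
        if len(lines) - 1 != N_SAMPLES:
            raise DatasetError(
                f"record {stem}: {len(lines) - 1} sample rows, "
                f"expected {N_SAMPLES}")
        try:
            samples = np.array(
                [[float(x) for x in line.split(",")] for line in lines[1:]])
        except ValueError as e:
            raise DatasetError(f"record {stem}: bad sample value ({e})")
        try:
            beat = RepresentativeBeat(samples, lead_names=header, beat_id=stem)
        except ValidationError as e:
            raise DatasetError(f"record {stem}: {e}")
        ann_path = path / f"{stem}.json"
        fids = None
        if ann_path.exists():
            fids = _fiducials_from_dict(json.loads(ann_path.read_text()), stem)
        items.append((beat, fids))
    return items
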