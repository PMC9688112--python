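"""Shared data model, CSV persistence, validation and protocol segmentation.

A recording is a uniformly sampled four-channel time series captured inside a
half-facepiece respirator: airflow (``af``, arbitrary transducer units,
reference channel), absolute pressure (``p``, kPa), temperature (``t_c``, °C)
and relative humidity (``rh``, %).  Recordings may carry condition labels —
respirator fit state or filter clogging level — as non-overlapping, time-ordered
segments.

On-disk format is plain CSV (header ``time_s,af,p_kpa,t_c,rh_pct``), with an
optional labels sidecar (``<stem>.labels.csv``, header
``start_s,end_s,kind,clog_pct``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "FIT_KINDS",
    "CLOG_LEVELS",
    "RespiraError",
    "FormatError",
    "SamplingError",
    "ValidationError",
    "SegmentLookupError",
    "InsufficientEventsError",
    "DegenerateDataError",
    "MissingDataError",
    "NoPairsError",
    "ConditionLabel",
    "Segment",
    "SignalRecording",
    "read_recording",
    "write_recording",
    "segment_recording",
]

#: channel name -> (attribute, physical range or None)
CHANNELS = ("af", "p", "t_c", "rh")

FIT_KINDS = ("fit_initial", "fit_loose", "fit_final")
CLOG_LEVELS = (0, 20, 40, 60, 80, 100)

# BME280-class sensor operating ranges; violations indicate a malformed file,
# not a clippable excursion.
_PHYS_RANGE = {"p": (30.0, 110.0), "t_c": (-40.0, 85.0), "rh": (0.0, 100.0)}

_TIME_TOL_S = 1e-9

_CSV_HEADER = ["time_s", "af", "p_kpa", "t_c", "rh_pct"]
_LABELS_HEADER = ["start_s", "end_s", "kind", "clog_pct"]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class RespiraError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RespiraError):
    """A file does not match the expected CSV dialect."""


class SamplingError(RespiraError):
    """The time grid is non-uniform or inconsistent with the expected rate."""


class ValidationError(RespiraError):
    """A recording violates a structural or physical-range invariant."""


class SegmentLookupError(RespiraError, KeyError):
    """A requested condition label is not among a recording's segments."""


class InsufficientEventsError(RespiraError):
    """Too few breathing events were detected to proceed."""


class DegenerateDataError(RespiraError):
    """A statistic is undefined on the given sample (e.g. zero variance)."""


class MissingDataError(RespiraError):
    """An expected (subject, condition) cell holds no observations."""


class NoPairsError(RespiraError):
    """No rate pairs could be matched between two event series."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionLabel:
    """A protocol condition: respirator fit state or filter clogging level.

    ``clog_pct`` is present exactly when ``kind == "clog_level"`` and must be
    one of the protocol's six levels (0, 20, 40, 60, 80, 100 % of the filter
    intake area occluded).
    """

    kind: str
    clog_pct: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "clog_level":
            if self.clog_pct is None:
                raise ValidationError("clog_level label requires clog_pct")
            if self.clog_pct not in CLOG_LEVELS:
                raise ValidationError(
                    f"clog_pct must be one of {CLOG_LEVELS}, got {self.clog_pct}"
                )
        elif self.kind in FIT_KINDS:
            if self.clog_pct is not None:
                raise ValidationError(f"{self.kind} label must not carry clog_pct")
        else:
            raise ValidationError(f"unknown condition kind {self.kind!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "clog_level":
            return f"clog_{self.clog_pct}"
        return self.kind


@dataclass(frozen=True)
class Segment:
    """A half-open labelled time interval ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: ConditionLabel

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"segment end ({self.end_s}) must exceed start ({self.start_s})"
            )


@dataclass
class SignalRecording:
    """A validated, uniformly sampled four-channel respirator recording.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds from recording start; ``t[0] == 0`` and the
        grid is uniform at ``1/fs`` (tolerance 1 ns).
    af, p, t_c, rh : ndarray
        Airflow (arbitrary units), pressure (kPa), temperature (°C) and
        relative humidity (%), all of equal length.
    fs : float
        Sampling rate in Hz (the device acquires at 10 Hz).
    subject_id : str
        Opaque subject label.
    segments : list of Segment
        Non-overlapping, time-ordered condition labels within the recording.
    """

    t: np.ndarray
    af: np.ndarray
    p: np.ndarray
    t_c: np.ndarray
    rh: np.ndarray
    fs: float
    subject_id: str = ""
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("t",) + CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- accessors ----------------------------------------------------------

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValidationError("recording must hold at least 2 samples")
        for name in CHANNELS:
            x = self.channel(name)
            if len(x) != n:
                raise ValidationError(
                    f"channel {name!r} length {len(x)} != time length {n}"
                )
            if not np.all(np.isfinite(x)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if abs(self.t[0]) > _TIME_TOL_S:
            raise ValidationError("time axis must start at 0 s")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.fs) > _TIME_TOL_S):
            raise SamplingError(
                f"non-uniform time grid: max deviation from 1/fs is "
                f"{np.max(np.abs(dt - 1.0 / self.fs)):.3g} s"
            )
        for name, (lo, hi) in _PHYS_RANGE.items():
            x = self.channel(name)
            if x.min() < lo or x.max() > hi:
                raise ValidationError(
                    f"channel {name!r} outside physical range [{lo}, {hi}]: "
                    f"observed [{x.min():.4g}, {x.max():.4g}]"
                )
        self._validate_segments()

    def _validate_segments(self) -> None:
        prev_end = None
        t0, t1 = float(self.t[0]), float(self.t[-1])
        for seg in self.segments:
            if seg.start_s < t0 - _TIME_TOL_S or seg.end_s > t1 + 1.0 / self.fs + _TIME_TOL_S:
                raise ValidationError(
                    f"segment [{seg.start_s}, {seg.end_s}) outside recording span"
                )
            if prev_end is not None and seg.start_s < prev_end - _TIME_TOL_S:
                raise ValidationError("segments overlap or are out of order")
            prev_end = seg.end_s


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _labels_path(path: Path) -> Path:
    return path.with_name(path.stem + ".labels.csv")


def write_recording(rec: SignalRecording, path) -> None:
    """Write a recording (and, if labelled, its sidecar) as CSV.

    Samples are written with 12 significant digits so a read-back reproduces
    every value to well below the 1 ns / 1e-9 round-trip tolerance.  If the
    recording carries no segments, no labels sidecar is emitted.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "af": rec.af,
            "p_kpa": rec.p,
            "t_c": rec.t_c,
            "rh_pct": rec.rh,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    if rec.segments:
        rows = []
        for seg in rec.segments:
            rows.append(
                {
                    "start_s": seg.start_s,
                    "end_s": seg.end_s,
                    "kind": seg.label.kind,
                    "clog_pct": "" if seg.label.clog_pct is None else seg.label.clog_pct,
                }
            )
        pd.DataFrame(rows, columns=_LABELS_HEADER).to_csv(
            _labels_path(path), index=False, float_format="%.12g"
        )


def read_recording(path, fs_expected: float = 10.0, subject_id: str = "") -> SignalRecording:
    """Read and validate a recording CSV (plus labels sidecar if present).

    The sampling rate is re-derived from the time column and checked against
    ``fs_expected``; a mismatch or non-uniform grid raises :class:`SamplingError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _CSV_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path.name}: time column is not strictly increasing")
    fs = 1.0 / float(np.mean(dt))
    if abs(fs - fs_expected) > 1e-6 * fs_expected:
        raise SamplingError(
            f"{path.name}: derived rate {fs:.6g} Hz != expected {fs_expected:.6g} Hz"
        )
    segments = _read_labels(_labels_path(path))
    return SignalRecording(
        t=t,
        af=df["af"].to_numpy(dtype=float),
        p=df["p_kpa"].to_numpy(dtype=float),
        t_c=df["t_c"].to_numpy(dtype=float),
        rh=df["rh_pct"].to_numpy(dtype=float),
        fs=fs_expected,
        subject_id=subject_id,
        segments=segments,
    )


def _read_labels(path: Path) -> list[Segment]:
    if not path.exists():
        return []
    df = pd.read_csv(path)
    missing = [c for c in _LABELS_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    segments = []
    for row in df.itertuples(index=False):
        pct = row.clog_pct
        pct = None if pd.isna(pct) else int(pct)
        segments.append(
            Segment(float(row.start_s), float(row.end_s), ConditionLabel(row.kind, pct))
        )
    return segments


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_recording(rec: SignalRecording, label: ConditionLabel) -> SignalRecording:
    """Return the sub-recording covering a label's half-open interval.

    Sample ``i`` belongs to the segment iff ``start_s <= t[i] < end_s``, so
    adjacent protocol phases never share samples.  The returned recording is
    re-zeroed (``t[0] == 0``) and carries a single segment spanning itself.
    """
    match = [s for s in rec.segments if s.label == label]
    if not match:
        raise SegmentLookupError(f"label {label} not found in recording segments")
    seg = match[0]
    i0 = int(np.ceil(seg.start_s * rec.fs - _TIME_TOL_S))
    i1 = int(np.ceil(seg.end_s * rec.fs - _TIME_TOL_S))
    i1 = min(i1, rec.n_samples)
    if i1 - i0 < 2:
        raise ValidationError(f"segment {label} holds fewer than 2 samples")
    sub = SignalRecording(
        t=rec.t[i0:i1] - rec.t[i0],
        af=rec.af[i0:i1].copy(),
        p=rec.p[i0:i1].copy(),
        t_c=rec.t_c[i0:i1].copy(),
        rh=rec.rh[i0:i1].copy(),
        fs=rec.fs,
        subject_id=rec.subject_id,
        segments=[],
    )
    sub.segments = [Segment(0.0, (i1 - i0) / rec.fs, label)]
    return sub


def _copy_with(rec: SignalRecording, **kw) -> SignalRecording:  # pragma: no cover
    return replace(rec, **kw)
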