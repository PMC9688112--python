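"""Instantaneous breathing rate (IBPM) and between-channel agreement.

The instantaneous rate between two consecutive same-kind events at times
``t[i-1] < t[i]`` is ``IBPM = 60 / (t[i] - t[i-1])`` breaths per minute,
timestamped at the later event.  Rates are computed from inspiratory events
(the series of detected "local maxima" in the per-channel convention);
expiratory-event rates are available for diagnostics.

Agreement between a test channel and the reference airflow channel is
summarized the standard way: Pearson correlation of the paired rates, plus a
Bland–Altman error analysis (bias = mean difference, limits of agreement =
bias ± 1.96 SD of the differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import NoPairsError, SignalRecording, ValidationError
from .events import EXPIRATORY, INSPIRATORY, PeakParams, detect_events
from .preprocess import FilterSpec

__all__ = [
    "IbpmSeries",
    "PairedRates",
    "AgreementReport",
    "ibpm_from_events",
    "ibpm_pipeline",
    "pair_series",
    "agreement",
]


@dataclass(frozen=True)
class IbpmSeries:
    """Instantaneous breaths-per-minute values with their event timestamps."""

    times_s: np.ndarray
    values_bpm: np.ndarray
    source_channel: str = ""

    def __len__(self) -> int:
        return len(self.values_bpm)

    def median(self) -> float:
        return float(np.median(self.values_bpm))


@dataclass(frozen=True)
class PairedRates:
    """One-to-one matched test/reference rate pairs."""

    times_s: np.ndarray  # test-event times
    test_bpm: np.ndarray
    ref_bpm: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.test_bpm)

    @property
    def differences(self) -> np.ndarray:
        return self.test_bpm - self.ref_bpm


@dataclass(frozen=True)
class AgreementReport:
    """Pearson + Bland–Altman agreement summary.

    ``r`` is NaN (with ``r_defined=False``) when either margin has zero
    variance — a constant rate series carries no correlation information and
    reporting 1.0 would overstate agreement.
    """

    r: float
    r_defined: bool
    bias_bpm: float
    sd_bpm: float
    loa_low_bpm: float
    loa_high_bpm: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "r": None if not self.r_defined else self.r,
            "r_defined": self.r_defined,
            "bias_bpm": self.bias_bpm,
            "sd_bpm": self.sd_bpm,
            "loa_low_bpm": self.loa_low_bpm,
            "loa_high_bpm": self.loa_high_bpm,
            "n_pairs": self.n_pairs,
        }


def ibpm_from_events(event_times_s, source_channel: str = "") -> IbpmSeries:
    """Instantaneous rate from consecutive same-kind event times.

    ``values[i] = 60 / (t[i+1] - t[i])``, timestamped at ``t[i+1]``; the
    series is one shorter than the event list.
    """
    t = np.asarray(event_times_s, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError("need at least 2 event times")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("event times must be strictly increasing")
    return IbpmSeries(times_s=t[1:], values_bpm=60.0 / dt, source_channel=source_channel)


def ibpm_pipeline(
    rec: SignalRecording,
    channel: str,
    params: PeakParams = PeakParams(),
    spec: FilterSpec = FilterSpec(),
    skip_first_cycles: int = 1,
    use_expiratory: bool = False,
) -> IbpmSeries:
    """Full rate pipeline on one channel: filter → events → IBPM.

    The first ``skip_first_cycles`` detected cycles are discarded (the
    protocol's deep synchronization breath, by default).
    """
    events = detect_events(rec, channel, params=params, spec=spec)
    kind = EXPIRATORY if use_expiratory else INSPIRATORY
    times = np.array([e.time_s for e in events if e.kind == kind])
    if skip_first_cycles > 0:
        times = times[skip_first_cycles:]
    if len(times) < 2:
        raise ValidationError(
            f"channel {channel!r}: fewer than 2 usable events after skipping"
        )
    return ibpm_from_events(times, source_channel=channel)


def pair_series(
    test: IbpmSeries, ref: IbpmSeries, max_lag_s: Optional[float] = None
) -> PairedRates:
    """Match test rates to reference rates one-to-one, nearest in time.

    Candidate matches within the lag window are accepted greedily in order of
    increasing time offset; each event is used at most once.  When
    ``max_lag_s`` is None the window adapts to the local breath period: a
    pair ``(i, j)`` is admissible if the offset is below half the shorter of
    the two local periods — a rate estimate should only be compared to the
    reference estimate of the *same* breath.
    """
    if len(test) == 0 or len(ref) == 0:
        raise NoPairsError("one of the rate series is empty")
    candidates = []
    for i, ti in enumerate(test.times_s):
        for j, tj in enumerate(ref.times_s):
            lag = abs(ti - tj)
            if max_lag_s is not None:
                allowed = max_lag_s
            else:
                allowed = 0.5 * min(60.0 / test.values_bpm[i], 60.0 / ref.values_bpm[j])
            if lag <= allowed:
                candidates.append((lag, i, j))
    if not candidates:
        raise NoPairsError("no rate pairs found within the lag window")
    candidates.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    matched = []
    for lag, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matched.append((test.times_s[i], test.values_bpm[i], ref.values_bpm[j]))
    matched.sort()
    times, tv, rv = (np.array(col) for col in zip(*matched))
    return PairedRates(times_s=times, test_bpm=tv, ref_bpm=rv)


def agreement(pairs: PairedRates) -> AgreementReport:
    """Pearson correlation and Bland–Altman statistics of matched rates."""
    if pairs.n_pairs < 2:
        raise ValidationError("agreement needs at least 2 pairs")
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    var_t = np.var(pairs.test_bpm)
    var_r = np.var(pairs.ref_bpm)
    if var_t == 0.0 or var_r == 0.0:
        r, defined = float("nan"), False
    else:
        r = float(np.corrcoef(pairs.test_bpm, pairs.ref_bpm)[0, 1])
        defined = True
    return AgreementReport(
        r=r,
        r_defined=defined,
        bias_bpm=bias,
        sd_bpm=sd,
        loa_low_bpm=bias - 1.96 * sd,
        loa_high_bpm=bias + 1.96 * sd,
        n_pairs=pairs.n_pairs,
    )
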