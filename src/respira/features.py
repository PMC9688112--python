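"""Per-cycle peak-to-peak amplitudes for fit and clogging evaluation.

A breath cycle runs from one inspiratory event to the next *on the same
channel*; its feature is the peak-to-peak amplitude (max − min) of the
band-pass-filtered signal over that cycle.  A loose respirator leaks, so the
in-mask pressure and humidity swings shrink; a clogged filter raises the
breathing effort, so the pressure swing grows — the per-cycle peak-to-peak
value is the carrier of both effects.

Feature tables are plain DataFrames with columns
``subject_id, channel, kind, clog_pct, cycle_index, p2p``; per-subject
aggregates (mean by default, so a 10-subject paired t-test has 9 degrees of
freedom) add ``n_cycles``.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_io import (
    CHANNELS,
    ConditionLabel,
    MissingDataError,
    SignalRecording,
    ValidationError,
    segment_recording,
)
from .events import BreathEvent, INSPIRATORY, PeakParams, detect_events
from .preprocess import FilterSpec, bandpass_zero_phase

__all__ = [
    "FEATURE_COLUMNS",
    "peak_to_peak_per_cycle",
    "extract_feature_table",
    "aggregate_features",
]

FEATURE_COLUMNS = ["subject_id", "channel", "kind", "clog_pct", "cycle_index", "p2p"]


def peak_to_peak_per_cycle(
    x, fs: float, insp_events: Union[Sequence[BreathEvent], Sequence[int], np.ndarray]
) -> np.ndarray:
    """Peak-to-peak amplitude of each complete cycle.

    ``insp_events`` may be BreathEvent objects or plain sample indices; each
    consecutive pair bounds one cycle and the peak-to-peak value is
    ``max(x) - min(x)`` over the closed index interval, giving one value per
    complete cycle.
    """
    x = np.asarray(x, dtype=float)
    if insp_events is not None and len(insp_events) > 0 and isinstance(insp_events[0], BreathEvent):
        idx = np.array([e.sample_index for e in insp_events if e.kind == INSPIRATORY])
    else:
        idx = np.asarray(insp_events, dtype=int)
    if len(idx) < 2:
        raise ValidationError("need at least 2 inspiratory events")
    if np.any(np.diff(idx) <= 0):
        raise ValidationError("event indices must be strictly increasing")
    if idx[0] < 0 or idx[-1] >= len(x):
        raise ValidationError("event index outside the series")
    out = np.empty(len(idx) - 1)
    for k in range(len(idx) - 1):
        seg = x[idx[k] : idx[k + 1] + 1]
        out[k] = seg.max() - seg.min()
    return out


def _cycles_for_segment(
    rec: SignalRecording,
    channel: str,
    params: PeakParams,
    spec: FilterSpec,
    use_filtered: bool,
    skip_first_cycles: int,
    trim_edge_cycles: int,
) -> np.ndarray:
    events = detect_events(rec, channel, params=params, spec=spec)
    x = rec.channel(channel)
    if use_filtered:
        x = bandpass_zero_phase(x, rec.fs, spec)
    p2p = peak_to_peak_per_cycle(x, rec.fs, events)
    if trim_edge_cycles > 0 and len(p2p) > 2 * trim_edge_cycles:
        p2p = p2p[trim_edge_cycles:-trim_edge_cycles]
    if skip_first_cycles > 0:
        p2p = p2p[skip_first_cycles:]
    return p2p


def extract_feature_table(
    recordings: Iterable[SignalRecording],
    channels: Sequence[str] = CHANNELS,
    params: PeakParams = PeakParams(),
    spec: FilterSpec = FilterSpec(),
    use_filtered: bool = True,
    skip_first_cycles: int = 0,
    trim_edge_cycles: int = 1,
) -> pd.DataFrame:
    """Build the per-cycle feature table from labelled recordings.

    Each recording's labelled segments are cut out (half-open intervals, so
    the deep synchronization breath that precedes the first segment never
    contributes) and every channel's per-cycle peak-to-peak amplitudes are
    computed on the band-pass-filtered signal by default (``use_filtered``
    switches to raw amplitudes).  ``trim_edge_cycles`` drops that many cycles
    at each end of every segment, where zero-phase filter edge transients can
    distort amplitudes.
    """
    rows = []
    for rec in recordings:
        if not rec.segments:
            raise ValidationError(
                f"recording {rec.subject_id!r} carries no condition segments"
            )
        for seg in rec.segments:
            sub = segment_recording(rec, seg.label)
            for ch in channels:
                p2p = _cycles_for_segment(
                    sub, ch, params, spec, use_filtered, skip_first_cycles,
                    trim_edge_cycles,
                )
                for k, v in enumerate(p2p):
                    rows.append(
                        {
                            "subject_id": rec.subject_id,
                            "channel": ch,
                            "kind": seg.label.kind,
                            "clog_pct": seg.label.clog_pct,
                            "cycle_index": k,
                            "p2p": float(v),
                        }
                    )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _condition_key(df: pd.DataFrame) -> pd.Series:
    key = df["kind"].astype(str).copy()
    clog = df["kind"] == "clog_level"
    key[clog] = "clog_" + df.loc[clog, "clog_pct"].astype("Int64").astype(str)
    return key


def aggregate_features(
    table: pd.DataFrame, statistic: str = "mean"
) -> pd.DataFrame:
    """Collapse per-cycle rows to one value per subject × channel × condition.

    The default mean aggregate makes the subject the unit of analysis, so a
    paired t-test across a 10-subject panel has n − 1 = 9 degrees of freedom.
    Raises :class:`MissingDataError` if any subject lacks cycles for a
    condition present elsewhere in the table.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    if table.empty:
        raise ValidationError("empty feature table")
    df = table.copy()
    df["condition"] = _condition_key(df)
    grouped = (
        df.groupby(["subject_id", "channel", "kind", "clog_pct", "condition"], dropna=False)["p2p"]
        .agg([statistic, "size"])
        .reset_index()
        .rename(columns={statistic: "p2p", "size": "n_cycles"})
    )
    subjects = sorted(df["subject_id"].unique())
    conditions = sorted(df["condition"].unique())
    channels = sorted(df["channel"].unique())
    have = set(zip(grouped["subject_id"], grouped["channel"], grouped["condition"]))
    for s in subjects:
        for ch in channels:
            for c in conditions:
                if (s, ch, c) not in have:
                    raise MissingDataError(
                        f"no cycles for subject {s!r}, channel {ch!r}, condition {c!r}"
                    )
    return grouped.drop(columns=["condition"]).sort_values(
        ["channel", "kind", "clog_pct", "subject_id"], ignore_index=True
    )
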