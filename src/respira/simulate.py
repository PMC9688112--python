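"""Synthetic four-channel respirator recordings for the three lab protocols.

No public dataset accompanies in-mask breathing studies of this kind, so the
generator stands in for the human-subject recordings.  It produces airflow
(reference transducer), pressure, temperature and relative-humidity channels
whose *event geometry* matches what the analysis assumes by construction:

* pressure and airflow are sinusoids in breathing phase, oriented so the
  inspiration onset (phase 0 mod 2π) is the falling inflection point of the
  cycle;
* temperature and humidity are tanh-sharpened alternating waves (exhaled air
  is warm and near-saturated, so these channels plateau) whose local maximum
  coincides with the inspiratory event and local minimum with the expiratory
  event.

Condition effects follow the directions the analysis is meant to discover:
a loose respirator leaks, attenuating the in-mask pressure and humidity
swings; filter clogging raises breathing effort and hence the pressure
swing (dramatically at full occlusion); temperature is deliberately left
condition-independent so that null findings are reproduced as well as
positive ones; the reference airflow is attenuated only at full occlusion.

Three protocols are emulated, each per subject of a panel:

``rates``
    Five 5-min recordings paced at 10, 13, 16, 19 and 22 breaths/min.
``fitting``
    One 15-min recording: 5 min fitted, 5 min loose straps, 5 min re-fitted.
``clogging``
    Six 5-min recordings at 0/20/40/60/80/100 % filter occlusion.

Every recording optionally starts with one deep (3× amplitude)
synchronization breath; labelled segments begin after it, separated by a
short randomized settle interval (under one breath) so segment boundaries
are not phase-locked to the synchronization breath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as _sig

from .core_io import (
    CLOG_LEVELS,
    ConditionLabel,
    Segment,
    SignalRecording,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SubjectPanel",
    "ProtocolRecording",
    "breathing_phase",
    "render_channels",
    "simulate_protocol",
]

PROTOCOLS = ("rates", "fitting", "clogging")
PROTOCOL_RATES_BPM = (10.0, 13.0, 16.0, 19.0, 22.0)

#: tanh sharpening factor for the temperature/humidity waveform
_TANH_K = 2.0
#: zero-phase low-pass cutoff (Hz) smoothing the tanh waveform
_SMOOTH_HZ = 1.0


def _default_clog_gain() -> dict[int, float]:
    # pressure-swing multiplier per occlusion level; ≥ 10-fold at 100 % so a
    # fully clogged filter dwarfs every other level
    return {0: 1.0, 20: 1.0, 40: 1.0, 60: 1.0, 80: 2.5, 100: 12.0}


def _default_clog_af_gain() -> dict[int, float]:
    # the reference airflow only collapses once the filter is fully occluded
    return {0: 1.0, 20: 1.0, 40: 1.0, 60: 1.0, 80: 1.0, 100: 0.5}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions.

    Amplitudes are half-amplitudes of the breathing oscillation per channel:
    ``amp_af`` in arbitrary transducer units, ``amp_p`` in kPa (in-mask
    pressure swings are of order 0.1 kPa), ``amp_t`` in °C and ``amp_rh``
    in %RH (exhaled air warms and humidifies the mask dead space).  Noise is
    additive white Gaussian with SD ``noise_sd_frac`` of the channel's
    effective half-amplitude, plus a Gaussian random-walk baseline drift with
    per-sample step ``drift_sd_frac`` of the half-amplitude (removed later by
    the band-pass).  ``t_noise_factor`` inflates the temperature channel's
    relative noise, reflecting its weaker condition coupling.
    """

    fs: float = 10.0
    rate_bpm: Union[float, Sequence[tuple[float, float]]] = 16.0
    duration_s: float = 300.0
    amp_af: float = 1.0
    amp_p: float = 0.1
    amp_t: float = 0.5
    amp_rh: float = 5.0
    baseline_p: float = 101.3
    baseline_t: float = 30.0
    baseline_rh: float = 70.0
    noise_sd_frac: float = 0.05
    drift_sd_frac: float = 0.01
    rate_jitter_frac: float = 0.03
    t_noise_factor: float = 1.5
    fit_leak: float = 0.4
    clog_gain: dict[int, float] = field(default_factory=_default_clog_gain)
    clog_af_gain: dict[int, float] = field(default_factory=_default_clog_af_gain)
    deep_breath: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amp_af", "amp_p", "amp_t", "amp_rh"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("noise_sd_frac", "drift_sd_frac", "rate_jitter_frac"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 < self.fit_leak <= 1.0:
            raise ValidationError("fit_leak must lie in (0, 1]")
        gains = [self.clog_gain[p] for p in CLOG_LEVELS if p in self.clog_gain]
        if any(b < a for a, b in zip(gains, gains[1:])):
            raise ValidationError("clog_gain must be non-decreasing in clog_pct")


@dataclass(frozen=True)
class SubjectPanel:
    """A panel of simulated subjects.

    Each subject carries a multiplicative amplitude factor, drawn once from a
    log-normal with σ = 0.2 (people breathe with different tidal volumes into
    the same mask volume), and a spontaneous breathing rate drawn uniformly
    from the normal adult range of 12–20 breaths/min.
    """

    n_subjects: int = 10
    amp_sigma: float = 0.2
    rate_range_bpm: tuple[float, float] = (12.0, 20.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("panel needs at least 2 subjects")

    def draw(self, rng: np.random.Generator) -> list[dict]:
        subjects = []
        for k in range(self.n_subjects):
            subjects.append(
                {
                    "subject_id": f"S{k + 1:02d}",
                    "amp_factor": float(np.exp(rng.normal(0.0, self.amp_sigma))),
                    "rate_bpm": float(rng.uniform(*self.rate_range_bpm)),
                }
            )
        return subjects


@dataclass(frozen=True)
class ProtocolRecording:
    """One simulated recording plus its protocol bookkeeping."""

    recording: SignalRecording
    subject_id: str
    protocol: str
    rate_bpm: Optional[float] = None  # paced rate (rates protocol only)
    condition: Optional[ConditionLabel] = None  # single-condition recordings


# ---------------------------------------------------------------------------
# breathing phase
# ---------------------------------------------------------------------------

def breathing_phase(
    duration_s: float,
    rate_schedule: Union[float, Sequence[tuple[float, float]]],
    rate_jitter_frac: float = 0.0,
    seed: Optional[int] = None,
    fs: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a monotone breathing phase φ(t); one cycle spans 2π.

    ``rate_schedule`` is either a constant rate in breaths/min or a
    piecewise-constant schedule ``[(start_s, rate_bpm), ...]``.  Each cycle's
    nominal duration is 60/rate at the cycle's start time, perturbed by a
    Gaussian cycle-to-cycle jitter with fractional SD ``rate_jitter_frac``
    (truncated to ±3 SD so durations stay positive).

    Returns ``(phi, cycle_starts_s)`` where ``phi`` is sampled on the uniform
    grid ``t = arange(round(duration_s*fs))/fs`` and ``cycle_starts_s`` holds
    the cycle boundary times (phase multiples of 2π), including 0.
    """
    if not duration_s > 0:
        raise ValidationError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    def rate_at(t: float) -> float:
        if np.isscalar(rate_schedule):
            return float(rate_schedule)
        r = None
        for start, rate in rate_schedule:
            if t >= start:
                r = rate
        if r is None:
            r = rate_schedule[0][1]
        return float(r)

    boundaries = [0.0]
    while boundaries[-1] < duration_s:
        r = rate_at(boundaries[-1])
        if not 4.0 < r < 60.0:
            raise ValidationError(f"breathing rate {r} BPM outside (4, 60)")
        dur = 60.0 / r
        if rate_jitter_frac > 0:
            # truncate at ±3 SD so cycle durations stay positive
            eps = float(np.clip(rng.normal(0.0, rate_jitter_frac),
                                -3.0 * rate_jitter_frac, 3.0 * rate_jitter_frac))
            dur *= 1.0 + eps
        boundaries.append(boundaries[-1] + dur)
    boundaries = np.asarray(boundaries)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase_knots = 2.0 * np.pi * np.arange(len(boundaries))
    phi = np.interp(t, boundaries, phase_knots)
    return phi, boundaries


# ---------------------------------------------------------------------------
# channel rendering
# ---------------------------------------------------------------------------

def _condition_gains(cfg: SimConfig, condition: Optional[ConditionLabel]) -> tuple[float, float, float]:
    """(p_gain, rh_gain, af_gain) for a condition; temperature has none."""
    if condition is None:
        return 1.0, 1.0, 1.0
    if condition.kind in ("fit_initial", "fit_final"):
        return 1.0, 1.0, 1.0
    if condition.kind == "fit_loose":
        return cfg.fit_leak, cfg.fit_leak, 1.0
    if condition.kind == "clog_level":
        pct = condition.clog_pct
        try:
            return cfg.clog_gain[pct], 1.0, cfg.clog_af_gain[pct]
        except KeyError as exc:
            raise ValidationError(f"no gain configured for clogging level {pct}%") from exc
    raise ValidationError(f"unknown condition kind {condition.kind!r}")


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    sos = _sig.butter(2, _SMOOTH_HZ, btype="lowpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def render_channels(
    phi: np.ndarray,
    cfg: SimConfig,
    condition: Optional[ConditionLabel] = None,
    subject_id: str = "",
    amp_factor: float = 1.0,
    envelope: Optional[np.ndarray] = None,
    segments: Optional[list[Segment]] = None,
    rng: Optional[np.random.Generator] = None,
    gain_arrays: Optional[dict[str, np.ndarray]] = None,
) -> SignalRecording:
    """Render the four channels from a breathing phase.

    Geometry (noise-free): airflow ∝ −sin φ and pressure = baseline − amp·sin φ,
    so φ ≡ 0 (mod 2π) — the inspiration onset — is the falling inflection
    point of both; temperature and humidity follow tanh(k·cos φ), peaking at
    the inspiratory event and bottoming at the expiratory one, then smoothed
    by a zero-phase low-pass (which preserves the extremum positions of the
    symmetric waveform).

    ``envelope`` scales all amplitudes per sample (deep-breath cycle);
    ``gain_arrays`` optionally supplies per-sample condition gains for the
    keys ``"p"``, ``"rh"``, ``"af"`` (used by the fitting protocol, where the
    condition changes within one continuous recording) and overrides
    ``condition``.  Noise and drift are added last.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1 or len(phi) < 2:
        raise ValidationError("phase must be a 1-D series of length >= 2")
    if np.any(np.diff(phi) < 0):
        raise ValidationError("phase must be monotone non-decreasing")
    n = len(phi)
    env = np.ones(n) if envelope is None else np.asarray(envelope, dtype=float)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if gain_arrays is None:
        p_gain, rh_gain, af_gain = _condition_gains(cfg, condition)
        p_gain = np.full(n, p_gain)
        rh_gain = np.full(n, rh_gain)
        af_gain = np.full(n, af_gain)
    else:
        p_gain = np.asarray(gain_arrays.get("p", np.ones(n)), dtype=float)
        rh_gain = np.asarray(gain_arrays.get("rh", np.ones(n)), dtype=float)
        af_gain = np.asarray(gain_arrays.get("af", np.ones(n)), dtype=float)

    s = np.sin(phi)
    w = np.tanh(_TANH_K * np.cos(phi)) / math.tanh(_TANH_K)
    w = _smooth(w, cfg.fs)

    amp_af = cfg.amp_af * amp_factor
    amp_p = cfg.amp_p * amp_factor
    amp_t = cfg.amp_t * amp_factor
    amp_rh = cfg.amp_rh * amp_factor

    af = -amp_af * af_gain * env * s
    p = cfg.baseline_p - amp_p * p_gain * env * s
    t_c = cfg.baseline_t + amp_t * env * w
    rh = cfg.baseline_rh + amp_rh * rh_gain * env * w

    def _noise(scale: float) -> np.ndarray:
        out = np.zeros(n)
        if cfg.noise_sd_frac > 0:
            out += rng.normal(0.0, cfg.noise_sd_frac * scale, n)
        if cfg.drift_sd_frac > 0:
            out += np.cumsum(rng.normal(0.0, cfg.drift_sd_frac * scale, n))
        return out

    af = af + _noise(amp_af)
    p = p + _noise(amp_p)
    t_c = t_c + _noise(amp_t * cfg.t_noise_factor)
    rh = rh + _noise(amp_rh)
    # humidity saturates physically; keep inside the sensor's reporting range
    rh = np.clip(rh, 0.0, 100.0)

    t = np.arange(n) / cfg.fs
    return SignalRecording(
        t=t, af=af, p=p, t_c=t_c, rh=rh, fs=cfg.fs,
        subject_id=subject_id, segments=segments or [],
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _single_condition_recording(
    cfg: SimConfig,
    rate_bpm: float,
    duration_s: float,
    condition: Optional[ConditionLabel],
    subject_id: str,
    amp_factor: float,
    rng: np.random.Generator,
) -> SignalRecording:
    """One recording at a constant nominal rate, deep breath prepended.

    When the recording carries a condition label, its segment starts a
    random fraction of a breath after the synchronization cycle so the
    segment boundary is not phase-locked to it.
    """
    t_db = 60.0 / rate_bpm if cfg.deep_breath else 0.0
    settle = float(rng.uniform(0.0, 60.0 / rate_bpm)) if condition is not None else 0.0
    total = t_db + settle + duration_s
    phi, _ = breathing_phase(
        total, rate_bpm, cfg.rate_jitter_frac, fs=cfg.fs, rng=rng
    )
    n = len(phi)
    env = np.ones(n)
    if cfg.deep_breath:
        env[phi < 2.0 * np.pi] = 3.0
    segments = None
    if condition is not None:
        t0 = _snap(t_db + settle, cfg.fs)
        segments = [Segment(t0, t0 + duration_s, condition)]
    return render_channels(
        phi, cfg, condition=condition, subject_id=subject_id,
        amp_factor=amp_factor, envelope=env, segments=segments, rng=rng,
    )


def _snap(t: float, fs: float) -> float:
    """Snap a boundary time onto the sample grid (floor)."""
    return math.floor(t * fs + 1e-9) / fs


def _fitting_recording(
    cfg: SimConfig, subject_id: str, amp_factor: float, rng: np.random.Generator,
    phase_s: float = 300.0,
) -> SignalRecording:
    rate = float(cfg.rate_bpm) if np.isscalar(cfg.rate_bpm) else 16.0
    t_db = 60.0 / rate if cfg.deep_breath else 0.0
    settle = float(rng.uniform(0.0, 60.0 / rate))
    total = t_db + settle + 3.0 * phase_s
    phi, _ = breathing_phase(total, rate, cfg.rate_jitter_frac, fs=cfg.fs, rng=rng)
    n = len(phi)
    t = np.arange(n) / cfg.fs
    env = np.ones(n)
    if cfg.deep_breath:
        env[phi < 2.0 * np.pi] = 3.0

    t0 = _snap(t_db + settle, cfg.fs)
    bounds = [t0, t0 + phase_s, t0 + 2.0 * phase_s, t0 + 3.0 * phase_s]
    labels = [ConditionLabel(k) for k in ("fit_initial", "fit_loose", "fit_final")]
    segments = [Segment(a, b, lab) for a, b, lab in zip(bounds[:-1], bounds[1:], labels)]

    leak = np.ones(n)
    loose = (t >= bounds[1]) & (t < bounds[2])
    leak[loose] = cfg.fit_leak
    gain_arrays = {"p": leak, "rh": leak, "af": np.ones(n)}
    return render_channels(
        phi, cfg, subject_id=subject_id, amp_factor=amp_factor,
        envelope=env, segments=segments, rng=rng, gain_arrays=gain_arrays,
    )


def simulate_protocol(
    protocol: str,
    panel: SubjectPanel = SubjectPanel(),
    cfg: SimConfig = SimConfig(),
    seed: Optional[int] = None,
) -> list[ProtocolRecording]:
    """Simulate one lab protocol across a subject panel.

    ``rates``   — five 5-min paced recordings per subject (10–22 BPM).
    ``fitting`` — one 15-min recording per subject, segmented
                  fitted/loose/fitted at the 5- and 10-min marks; the loose
                  phase leaks, attenuating pressure and humidity swings.
    ``clogging``— six 5-min recordings per subject at 0–100 % occlusion,
                  each breathed at the subject's spontaneous rate.

    The result is deterministic in ``seed`` (falling back to ``cfg.seed``).
    """
    if protocol not in PROTOCOLS:
        raise ValidationError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    subjects = panel.draw(master)
    out: list[ProtocolRecording] = []
    for subj in subjects:
        sub_rng = np.random.default_rng(master.integers(2**31))
        if protocol == "rates":
            for rate in PROTOCOL_RATES_BPM:
                rec = _single_condition_recording(
                    cfg, rate, cfg.duration_s, None,
                    subj["subject_id"], subj["amp_factor"], sub_rng,
                )
                out.append(ProtocolRecording(rec, subj["subject_id"], protocol, rate_bpm=rate))
        elif protocol == "fitting":
            rec = _fitting_recording(cfg, subj["subject_id"], subj["amp_factor"], sub_rng)
            out.append(ProtocolRecording(rec, subj["subject_id"], protocol))
        else:  # clogging
            for pct in CLOG_LEVELS:
                label = ConditionLabel("clog_level", pct)
                rec = _single_condition_recording(
                    cfg, subj["rate_bpm"], cfg.duration_s, label,
                    subj["subject_id"], subj["amp_factor"], sub_rng,
                )
                out.append(
                    ProtocolRecording(rec, subj["subject_id"], protocol, condition=label)
                )
    return out


def with_overrides(cfg: SimConfig, **kw) -> SimConfig:
    """Return a copy of ``cfg`` with fields replaced (convenience)."""
    return replace(cfg, **kw)
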