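"""Synthetic-generator geometry, protocol structure and reproducibility."""

import numpy as np
import pytest

from respira import (
    ConditionLabel,
    SimConfig,
    SubjectPanel,
    ValidationError,
    breathing_phase,
    render_channels,
    simulate_protocol,
)
from respira.events import detect_events, INSPIRATORY
from respira.features import peak_to_peak_per_cycle
from respira.preprocess import bandpass_zero_phase


def _strict_maxima(x):
    return [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]


def _strict_minima(x):
    return [i for i in range(1, len(x) - 1) if x[i - 1] > x[i] < x[i + 1]]


class TestBreathingPhase:
    def test_exact_cycle_count_without_jitter(self):
        phi, bounds = breathing_phase(60.0, 12.0, 0.0, fs=10.0)
        assert len(bounds) - 1 == 12
        assert bounds[-1] == pytest.approx(60.0, abs=1e-12)
        assert np.all(np.diff(phi) >= 0)

    def test_dominant_frequency_matches_rate(self):
        phi, _ = breathing_phase(600.0, 16.0, 0.0, fs=10.0)
        x = np.sin(phi)
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=0.1)
        assert freqs[np.argmax(spec)] == pytest.approx(16.0 / 60.0, abs=freqs[1])

    def test_cycle_duration_cv_matches_jitter(self):
        phi, bounds = breathing_phase(800.0, 16.0, 0.03, seed=11, fs=10.0)
        durations = np.diff(bounds)[:200]
        cv = durations.std() / durations.mean()
        assert cv == pytest.approx(0.03, abs=0.006)

    def test_piecewise_schedule_changes_rate(self):
        schedule = [(0.0, 10.0), (60.0, 20.0)]
        _, bounds = breathing_phase(120.0, schedule, 0.0, fs=10.0)
        durations = np.diff(bounds)
        assert durations[0] == pytest.approx(6.0)
        assert durations[-1] == pytest.approx(3.0)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValidationError):
            breathing_phase(0.0, 12.0)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValidationError):
            breathing_phase(60.0, 90.0)


class TestRenderChannels:
    def test_temperature_maxima_count_matches_cycles(self, noise_free_cfg):
        phi, _ = breathing_phase(60.0, 12.0, 0.0, fs=10.0)
        rec = render_channels(phi, noise_free_cfg)
        n_max = len(_strict_maxima(rec.t_c))
        assert abs(n_max - 12) <= 1

    def test_pressure_inflections_align_with_temperature_peaks(self, noise_free_cfg):
        """Cross-channel event geometry: dP/dt minima sit at T maxima."""
        phi, _ = breathing_phase(120.0, 14.0, 0.0, fs=10.0)
        rec = render_channels(phi, noise_free_cfg)
        dp = np.gradient(rec.p) * rec.fs
        dp_minima = _strict_minima(dp)
        t_maxima = _strict_maxima(rec.t_c)
        interior = [i for i in dp_minima if 20 < i < len(dp) - 20]
        for i in interior:
            assert min(abs(i - j) for j in t_maxima) <= 1

    def test_full_clog_pressure_ratio_at_least_tenfold(self, noise_free_cfg):
        """The 100 % occlusion level dwarfs the unclogged pressure swing."""
        phi, _ = breathing_phase(120.0, 14.0, 0.0, fs=10.0)
        med = {}
        for pct in (0, 100):
            rec = render_channels(phi, noise_free_cfg, ConditionLabel("clog_level", pct))
            events = detect_events(rec, "p")
            x = bandpass_zero_phase(rec.p, rec.fs)
            med[pct] = np.median(peak_to_peak_per_cycle(x, rec.fs, events))
        assert med[100] / med[0] >= 10.0

    def test_loose_condition_attenuates_p_and_rh_not_t(self, noise_free_cfg):
        phi, _ = breathing_phase(120.0, 14.0, 0.0, fs=10.0)
        fitted = render_channels(phi, noise_free_cfg, ConditionLabel("fit_initial"))
        loose = render_channels(phi, noise_free_cfg, ConditionLabel("fit_loose"))
        for ch in ("p", "rh"):
            assert np.ptp(loose.channel(ch)) < 0.6 * np.ptp(fitted.channel(ch))
        assert np.ptp(loose.t_c) == pytest.approx(np.ptp(fitted.t_c), rel=1e-9)

    def test_unconfigured_clog_level_rejected(self, noise_free_cfg):
        from dataclasses import replace

        phi, _ = breathing_phase(30.0, 14.0, 0.0, fs=10.0)
        sparse = replace(noise_free_cfg, clog_gain={0: 1.0})
        with pytest.raises(ValidationError, match="no gain configured"):
            render_channels(phi, sparse, ConditionLabel("clog_level", 40))
        # unknown condition kinds cannot even be constructed
        with pytest.raises(ValidationError):
            ConditionLabel("half_fitted")


class TestProtocols:
    def test_rates_protocol_counts_and_lengths(self):
        cfg = SimConfig()
        recs = simulate_protocol("rates", SubjectPanel(n_subjects=2), cfg, seed=5)
        mine = [pr for pr in recs if pr.subject_id == "S01"]
        assert len(mine) == 5
        for pr in mine:
            expected = cfg.duration_s + 60.0 / pr.rate_bpm  # deep breath prepended
            assert pr.recording.n_samples == round(expected * cfg.fs)

    def test_clogging_protocol_yields_sixty_recordings(self, clogging_recordings):
        assert len(clogging_recordings) == 60
        levels = {pr.condition.clog_pct for pr in clogging_recordings}
        assert levels == {0, 20, 40, 60, 80, 100}

    def test_fitting_protocol_segment_structure(self, fitting_recordings):
        assert len(fitting_recordings) == 10
        rec = fitting_recordings[0].recording
        kinds = [s.label.kind for s in rec.segments]
        assert kinds == ["fit_initial", "fit_loose", "fit_final"]
        for seg in rec.segments:
            assert seg.end_s - seg.start_s == pytest.approx(300.0)

    def test_same_seed_reproduces_bit_identical_output(self):
        cfg = SimConfig(duration_s=60.0)
        a = simulate_protocol("clogging", SubjectPanel(n_subjects=2), cfg, seed=9)
        b = simulate_protocol("clogging", SubjectPanel(n_subjects=2), cfg, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.recording.p, pb.recording.p)
            np.testing.assert_array_equal(pa.recording.rh, pb.recording.rh)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValidationError):
            simulate_protocol("swimming", SubjectPanel(n_subjects=2))

    def test_clog_pressure_medians_monotone(self, clogging_table):
        p = clogging_table[clogging_table.channel == "p"]
        medians = p.groupby("clog_pct")["p2p"].median()
        vals = medians.loc[[0, 20, 40, 60, 80, 100]].to_numpy()
        # equal-gain levels may wiggle by noise; allow 5 % slack there
        assert np.all(np.diff(vals) >= -0.05 * vals[:-1])
        assert vals[4] > 2.0 * vals[3]  # 80 % level clearly above 60 %
        assert vals[5] > 4.0 * vals[4]  # 100 % level clearly above 80 %


class TestConfigValidation:
    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(amp_p=-0.1)

    def test_decreasing_clog_gain_rejected(self):
        bad = {0: 1.0, 20: 0.5, 40: 1.0, 60: 1.0, 80: 2.5, 100: 12.0}
        with pytest.raises(ValidationError):
            SimConfig(clog_gain=bad)

    def test_fit_leak_bounds(self):
        with pytest.raises(ValidationError):
            SimConfig(fit_leak=0.0)
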