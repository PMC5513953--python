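"""Beat detection: peaks, IMF selection, stitching, PPI correction, CWT envelopes."""

import numpy as np
import pytest
from scipy.signal import periodogram

from dusqa.beats import (
    BeatSequence,
    CycleEnvelope,
    NoBeatsError,
    correct_ppis,
    cwt_valve_band,
    cycle_envelopes,
    detect_beats,
    detect_peaks,
    gate_physiological,
    select_optimal_imf,
    stitch_windows,
)
from dusqa.emd import IMFDecomposition

FS = 4000.0


class TestDetectPeaks:
    def test_single_peak(self):
        assert detect_peaks(np.array([0.0, 1.0, 0.0])).tolist() == [1]

    def test_monotone_has_no_peaks(self):
        assert detect_peaks(np.arange(10.0)).size == 0

    def test_2hz_sinusoid_peak_locations(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        peaks = detect_peaks(x)
        # argmax of each period: 0.125 s and 0.625 s (then 1.125, 1.625)
        expected = np.array([500, 2500, 4500, 6500])
        assert peaks.size == 4
        assert np.max(np.abs(peaks - expected)) <= 1


def _am_burst_imf(t, burst_times, carrier_hz=300.0, width=0.03):
    env = sum(np.exp(-0.5 * ((t - b) / width) ** 2) for b in burst_times)
    return env * np.sin(2 * np.pi * carrier_hz * t)


class TestSelectOptimalIMF:
    def test_periodic_envelope_wins_over_jittered(self):
        t = np.arange(int(4 * FS)) / FS
        periodic = np.arange(0.3, 3.9, 0.45)
        rng = np.random.default_rng(0)
        jittered = periodic + rng.uniform(-0.1, 0.1, periodic.size)
        imfs = [_am_burst_imf(t, jittered, 600.0),
                _am_burst_imf(t, periodic, 300.0)]
        decomp = IMFDecomposition(imfs=imfs, residual=np.zeros(t.size))
        idx, peaks = select_optimal_imf(t, decomp, FS)
        assert idx == 2
        # peaks land on the periodic bursts
        assert peaks.size == periodic.size
        assert np.max(np.abs(peaks / FS - periodic)) < 0.05

    def test_single_valid_imf_returned(self):
        t = np.arange(int(4 * FS)) / FS
        imfs = [np.zeros(t.size), _am_burst_imf(t, np.arange(0.3, 3.9, 0.45))]
        decomp = IMFDecomposition(imfs=imfs, residual=np.zeros(t.size))
        idx, _ = select_optimal_imf(t, decomp, FS)
        assert idx == 2

    def test_tie_breaks_to_lowest_index(self):
        t = np.arange(int(4 * FS)) / FS
        imf = _am_burst_imf(t, np.arange(0.3, 3.9, 0.45))
        decomp = IMFDecomposition(imfs=[imf, imf.copy()], residual=np.zeros(t.size))
        idx, _ = select_optimal_imf(t, decomp, FS)
        assert idx == 1

    def test_all_excluded_raises(self):
        t = np.arange(int(4 * FS)) / FS
        decomp = IMFDecomposition(imfs=[np.zeros(t.size)], residual=np.zeros(t.size))
        with pytest.raises(NoBeatsError):
            select_optimal_imf(t, decomp, FS)


class TestStitchWindows:
    def test_duplicate_at_seam_kept_once(self):
        w1 = np.array([1000, 2600, 4200, 5800, 7400, 9000, 10600, 12200, 13800])
        w2 = w1[w1 >= 12000]  # identical peaks in the overlap
        merged = stitch_windows([w1, w2], [0, 12000], 16000, 4000)
        assert np.array_equal(merged, w1)

    def test_peak_only_in_later_window_kept(self):
        w1 = np.array([1000, 2600, 4200, 5800, 7400, 9000, 10600])
        w2 = np.array([12200, 13800, 15400])
        merged = stitch_windows([w1, w2], [0, 12000], 16000, 4000)
        assert set(w2.tolist()) <= set(merged.tolist())

    def test_close_seam_peaks_merged_to_earlier(self):
        # median PPI 1600 samples (400 ms); 10 ms apart = 40 samples < 0.2*1600
        w1 = np.array([1000, 2600, 4200, 5800, 7400, 9000, 10600, 12200])
        w2 = np.array([12240, 13800])
        merged = stitch_windows([w1, w2], [0, 12000], 16000, 4000)
        assert 12200 in merged and 12240 not in merged


class TestCorrectPPIs:
    @staticmethod
    def _seq(ppis):
        beats = np.concatenate([[0], np.cumsum(ppis)])
        return BeatSequence(beats, FS)

    def test_outlier_middle_replaced(self):
        out = correct_ppis(self._seq([500, 500, 700, 500, 500]))
        assert np.diff(out.beat_samples)[2] == 500  # 40% > 20% -> replaced

    def test_within_tolerance_unchanged(self):
        seq = self._seq([500, 500, 580, 500, 500])
        out = correct_ppis(seq)
        assert np.array_equal(out.beat_samples, seq.beat_samples)  # 16% < 20%

    def test_all_equal_unchanged(self):
        seq = self._seq([500] * 8)
        out = correct_ppis(seq)
        assert np.array_equal(out.beat_samples, seq.beat_samples)

    def test_too_few_ppis_returned_unchanged(self):
        seq = self._seq([500, 600, 500])
        assert correct_ppis(seq) is seq

    def test_idempotent_on_jittered_trains(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ppis = rng.normal(1700, 80, 40)
            ppis[rng.integers(5, 35)] *= 1.5  # one outlier
            once = correct_ppis(self._seq(np.round(ppis).astype(int)))
            twice = correct_ppis(once)
            assert np.array_equal(once.beat_samples, twice.beat_samples)


class TestGate:
    def test_short_intervals_merged(self):
        beats = np.array([0, 700, 1700, 2400, 3400])  # 700 < 60/210*4000
        out = gate_physiological(beats, FS)
        assert np.all(np.diff(out) >= FS * 60 / 210)

    def test_long_interval_subdivided(self):
        beats = np.concatenate([np.arange(0, 17000, 1700),
                                [15300 + 2 * 1700 + 1700]])  # one missed beat
        out = gate_physiological(np.unique(beats), FS)
        bpm = 60 * FS / np.diff(out)
        assert bpm.min() >= 90 and bpm.max() <= 210


class TestEndToEndBeats:
    def test_recovers_planted_beats_and_bpm_gate(self, clean_recording, cfg):
        rec, truth = clean_recording
        beats = detect_beats(rec.samples, rec.fs, cfg)
        tol = int(0.05 * rec.fs)
        matched = sum(np.min(np.abs(beats.beat_samples - tb)) <= tol
                      for tb in truth.beat_samples)
        assert matched / truth.beat_samples.size >= 0.95
        bpm = 60 * rec.fs / beats.ppis
        assert bpm.min() >= 89.5 and bpm.max() <= 210.5


class TestCWT:
    def test_500hz_passband_vs_1500hz(self):
        t = np.arange(int(2 * FS)) / FS
        out_lo = cwt_valve_band(np.sin(2 * np.pi * 500 * t), FS)
        out_hi = cwt_valve_band(np.sin(2 * np.pi * 1500 * t), FS)
        assert np.mean(out_lo) / np.mean(out_hi) > 2.0

    def test_zero_input(self):
        assert np.allclose(cwt_valve_band(np.zeros(8000), FS), 0.0)

    def test_impulse_energy_matches_wavelet_norm(self):
        x = np.zeros(4000)
        x[2000] = 1.0
        out = cwt_valve_band(x, FS)
        # kernel is normalised to unit continuous L2 energy
        assert abs(np.sum(out**2) - 1.0) < 0.01


class TestCycleEnvelopes:
    def _mag(self, n=16000, bumps=(0.25, 0.65), period=4000):
        """Rectified-carrier magnitude with two Gaussian bumps per cycle."""
        t = np.arange(n)
        env = np.full(n, 0.05)
        for start in range(0, n, period):
            for frac in bumps:
                c = start + frac * period
                env = env + np.exp(-0.5 * ((t - c) / 120.0) ** 2)
        carrier = np.abs(np.sin(2 * np.pi * 300.0 * t / FS)) + 0.05
        return env * carrier

    def test_cycles_are_normalised(self):
        beats = BeatSequence(np.arange(0, 16000, 4000), FS)
        cycles = cycle_envelopes(self._mag(), beats)
        for c in cycles:
            assert abs(np.mean(c.values)) < 1e-9
            assert abs(np.std(c.values) - 1.0) < 1e-9

    def test_two_bumps_per_cycle_retained(self):
        beats = BeatSequence(np.arange(0, 16000, 4000), FS)
        for c in cycle_envelopes(self._mag(), beats):
            v = c.values
            n_max = np.sum((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
                           & (v[1:-1] > 0.5 * v.max()))
            assert n_max == 2

    def test_smoothing_removes_high_frequency_ripple(self):
        n = 16000
        t = np.arange(n) / FS
        mag = self._mag(n) + 0.2 * (1 + np.sin(2 * np.pi * 500 * t)) / 2
        beats = BeatSequence(np.array([0, n - 1]), FS)
        cycles = cycle_envelopes(mag, beats)
        f, pxx = periodogram(cycles[0].values, fs=FS)
        ripple = np.sum(pxx[(f > 450) & (f < 550)])
        assert ripple / np.sum(pxx) < 1e-4  # > 40 dB down from a dominant line

    def test_zero_variance_cycle_dropped(self):
        mag = np.ones(8000)
        beats = BeatSequence(np.array([0, 4000, 7999]), FS)
        assert cycle_envelopes(mag, beats) == []
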