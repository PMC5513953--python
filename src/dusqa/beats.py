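"""Beat detection and per-cycle envelope extraction for DUS audio.

Cardiac cycles are located by decomposing 4-s windows (3-s stride, 1-s
overlap) with EMD, enveloping each of the first four IMFs through its detected
peaks, and keeping the IMF whose envelope peak-to-peak intervals (PPIs) have
the smallest standard deviation. Window peak lists are stitched at the 1-s
overlaps, gated to a physiological heart-rate range, and cleaned with a moving
5-PPI correction.

For template construction the signal is then transformed with a continuous
wavelet transform (order-2 complex Gaussian mother) whose magnitude envelope,
segmented at the beat locations and normalised per cycle, forms the
beat-aligned cycle envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, fftconvolve, sosfiltfilt

from dusqa.config import PipelineConfig
from dusqa.emd import IMFDecomposition, sift

logger = logging.getLogger(__name__)


class NoBeatsError(RuntimeError):
    """No IMF of a window produced at least two envelope peaks."""


@dataclass
class BeatSequence:
    """Detected beat locations (sample indices at the working rate)."""

    beat_samples: np.ndarray
    fs: float
    source_imf: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_samples = np.asarray(self.beat_samples, dtype=np.int64)
        if self.beat_samples.size and np.any(np.diff(self.beat_samples) <= 0):
            raise ValueError("beat_samples must be strictly increasing")

    @property
    def ppis(self) -> np.ndarray:
        """Peak-to-peak intervals in samples."""
        return np.diff(self.beat_samples)

    @property
    def n_beats(self) -> int:
        return int(self.beat_samples.size)


@dataclass
class CycleEnvelope:
    """Normalised (zero-mean, unit-SD) envelope of one cardiac cycle."""

    values: np.ndarray
    onset_sample: int

    @property
    def length_samples(self) -> int:
        return int(self.values.size)


def detect_peaks(x: np.ndarray) -> np.ndarray:
    """Peak indices by the positive-first-derivative / negative-second-derivative rule.

    A sample ``i`` is a peak when the first difference changes from positive to
    non-positive at ``i`` and the second difference there is negative.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        return np.array([], dtype=np.int64)
    d1 = np.diff(x)
    d2 = x[2:] - 2.0 * x[1:-1] + x[:-2]
    mask = (d1[:-1] > 0) & (d1[1:] <= 0) & (d2 < 0)
    return np.where(mask)[0] + 1


def _smooth_lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass."""
    sos = butter(4, cutoff_hz / (fs / 2.0), output="sos")
    return sosfiltfilt(sos, x)


def _peak_envelope(x: np.ndarray) -> np.ndarray | None:
    """Spline envelope through the detected peaks of ``x`` (None if < 4 peaks)."""
    peaks = detect_peaks(x)
    if peaks.size < 4:
        return None
    idx = peaks
    val = x[peaks]
    if idx[0] != 0:
        idx = np.concatenate([[0], idx])
        val = np.concatenate([[val[0]], val])
    if idx[-1] != x.size - 1:
        idx = np.concatenate([idx, [x.size - 1]])
        val = np.concatenate([val, [val[-1]]])
    return CubicSpline(idx, val)(np.arange(x.size))


def imf_envelope(imf: np.ndarray, fs: float, smooth_cutoff_hz: float = 25.0) -> np.ndarray | None:
    """Smoothed amplitude envelope of an IMF (spline through peaks, low-passed)."""
    env = _peak_envelope(imf)
    if env is None:
        return None
    return _smooth_lowpass(env, fs, smooth_cutoff_hz)


def _envelope_beat_peaks(env: np.ndarray, peak_floor: float) -> np.ndarray:
    """Envelope peaks, discarding those below a fraction of the 95th percentile.

    Raw spline envelopes of noisy IMFs carry many tiny maxima between bursts;
    the amplitude floor keeps only peaks of burst scale.
    """
    peaks = detect_peaks(env)
    if peaks.size == 0:
        return peaks
    floor = peak_floor * np.percentile(env, 95)
    return peaks[env[peaks] >= floor]


def _merge_keep_larger(peaks: np.ndarray, amps: np.ndarray,
                       min_ppi: float) -> np.ndarray:
    """Greedy merge of peaks closer than ``min_ppi``, keeping the larger one.

    With two Doppler bursts per cardiac cycle this locks the peak train onto
    the stronger (systolic) burst instead of alternating between the two.
    """
    if peaks.size < 2:
        return peaks
    kept_i = [int(peaks[0])]
    kept_a = [float(amps[0])]
    for p, a in zip(peaks[1:], amps[1:]):
        if p - kept_i[-1] < min_ppi:
            if a > kept_a[-1]:
                kept_i[-1], kept_a[-1] = int(p), float(a)
        else:
            kept_i.append(int(p))
            kept_a.append(float(a))
    return np.asarray(kept_i, dtype=np.int64)


def select_optimal_imf(window: np.ndarray, decomp: IMFDecomposition, fs: float,
                       smooth_cutoff_hz: float = 25.0,
                       peak_floor: float = 0.10,
                       bpm_max: float = 210.0) -> tuple[int, np.ndarray]:
    """Pick the IMF whose envelope PPIs have the lowest standard deviation.

    Per IMF, envelope peaks are first gated to the physiological minimum
    interval ``60/bpm_max`` (keeping the larger of two close peaks). The
    selection metric is the SD of the gated peak-to-peak intervals divided by
    the peak salience (mean peak height over the envelope median): without
    gating and salience normalisation, noise-dominated low-frequency IMFs
    produce short, regular, low-amplitude peak trains whose raw PPI SD
    spuriously undercuts the cardiac IMF.

    Returns the 1-based IMF index and that IMF's gated envelope peak indices
    (window-relative samples). IMFs with fewer than two gated peaks are
    excluded; ties resolve to the lowest index. Raises :class:`NoBeatsError`
    when every IMF is excluded.
    """
    if decomp.n_imfs == 0:
        raise NoBeatsError("decomposition has no IMFs")
    min_ppi = fs * 60.0 / bpm_max
    best_idx, best_peaks, best_score = -1, None, np.inf
    for i, imf in enumerate(decomp.imfs[:4]):
        env = imf_envelope(imf, fs, smooth_cutoff_hz)
        if env is None:
            continue
        peaks = _envelope_beat_peaks(env, peak_floor)
        if peaks.size < 2:
            continue
        peaks = _merge_keep_larger(peaks, env[peaks], min_ppi)
        if peaks.size < 2:
            continue
        sd = float(np.std(np.diff(peaks)))
        med = float(np.median(env))
        salience = float(np.mean(env[peaks])) / med if med > 0 else 1.0
        score = sd / max(salience, 1e-12)
        if score < best_score:
            best_idx, best_peaks, best_score = i + 1, peaks, score
    if best_peaks is None:
        raise NoBeatsError("no IMF produced >= 2 envelope peaks")
    return best_idx, best_peaks


def stitch_windows(window_peaks: list[np.ndarray], window_starts: list[int],
                   window_len: int, overlap: int) -> np.ndarray:
    """Merge per-window absolute peak indices across 1-s window overlaps.

    Inside each overlap region, a peak of the later window closer than
    0.2x the local median PPI to an already-kept peak is dropped (the earlier
    one is kept); peaks present in only one window survive.
    """
    merged: list[int] = []
    for peaks, start in zip(window_peaks, window_starts):
        peaks = np.asarray(peaks, dtype=np.int64)
        if not merged:
            merged.extend(peaks.tolist())
            continue
        overlap_end = start + overlap
        existing = np.asarray(merged, dtype=np.int64)
        local_ppis = np.diff(existing[-9:])
        med_ppi = float(np.median(local_ppis)) if local_ppis.size else float(overlap)
        tol = 0.2 * med_ppi
        for p in peaks:
            if p < overlap_end:
                # overlap region: merge near-duplicates, keep the earlier
                if existing.size and np.min(np.abs(existing - p)) < tol:
                    continue
            if merged and p <= merged[-1]:
                continue
            merged.append(int(p))
            existing = np.asarray(merged, dtype=np.int64)
    return np.asarray(sorted(set(merged)), dtype=np.int64)


def gate_physiological(beats: np.ndarray, fs: float, bpm_min: float = 90.0,
                       bpm_max: float = 210.0) -> np.ndarray:
    """Constrain intervals to the physiological fetal heart-rate range.

    Intervals shorter than ``60/bpm_max`` are removed greedily (the earlier
    beat is kept, the later one dropped); intervals longer than ``60/bpm_min``
    are subdivided by the local median PPI (missed-beat interpolation).
    """
    beats = np.asarray(beats, dtype=np.int64)
    if beats.size < 2:
        return beats
    min_ppi = fs * 60.0 / bpm_max
    max_ppi = fs * 60.0 / bpm_min
    kept = [int(beats[0])]
    for b in beats[1:]:
        if b - kept[-1] >= min_ppi:
            kept.append(int(b))
    ppis = np.diff(kept)
    in_range = ppis[(ppis >= min_ppi) & (ppis <= max_ppi)]
    med = float(np.median(in_range)) if in_range.size else float(np.median(ppis))
    out = [kept[0]]
    for b in kept[1:]:
        gap = b - out[-1]
        if gap > max_ppi and med > 0:
            # interpolate missed beats evenly across the long interval
            k = max(int(round(gap / med)), int(np.ceil(gap / max_ppi)))
            prev = out[-1]
            for j in range(1, k):
                out.append(int(round(prev + j * gap / k)))
        out.append(int(b))
    return np.unique(np.asarray(out, dtype=np.int64))


def correct_ppis(beats: BeatSequence, tol_frac: float = 0.2) -> BeatSequence:
    """Moving 5-PPI outlier correction.

    Slides a 5-interval window left to right; when the middle interval differs
    from the mean of the other four by more than ``tol_frac`` of that mean,
    the middle interval is set to that mean by relocating its trailing beat
    (the following interval absorbs the shift, and later windows see the
    corrected values). Only anomalous beats move; an accurate tail is never
    translated wholesale.
    """
    pos = beats.beat_samples.astype(np.float64).copy()
    if pos.size < 6:
        logger.warning("correct_ppis: fewer than 5 PPIs, returned unchanged")
        return beats
    for i in range(2, pos.size - 3):
        # interval i runs from beat i to beat i+1
        ppis = np.diff(pos)
        others = np.concatenate([ppis[i - 2:i], ppis[i + 1:i + 3]])
        m = float(np.mean(others))
        if m > 0 and abs(ppis[i] - m) > tol_frac * m:
            pos[i + 1] = pos[i] + m
    out = np.round(pos).astype(np.int64)
    out = out[np.concatenate([[True], np.diff(out) > 0])]
    return BeatSequence(out, beats.fs, source_imf=list(beats.source_imf))


def detect_beats(samples: np.ndarray, fs: float,
                 cfg: PipelineConfig | None = None) -> BeatSequence:
    """End-to-end beat detection: EMD windows -> optimal IMF -> stitch -> gate -> correct."""
    cfg = cfg or PipelineConfig()
    x = np.asarray(samples, dtype=np.float64)
    win = int(round(cfg.emd_window_s * fs))
    stride = int(round(cfg.emd_window_stride_s * fs))
    overlap = win - stride
    starts = list(range(0, max(x.size - win, 0) + 1, stride))
    if not starts:
        starts = [0]
        win = x.size
    elif starts[-1] < x.size - win:
        starts.append(x.size - win)  # cover the record tail
    window_peaks: list[np.ndarray] = []
    window_starts: list[int] = []
    sources: list[int] = []
    for s in starts:
        chunk = x[s:s + win]
        if chunk.size < 16:
            continue
        decomp = sift(chunk, max_imfs=cfg.max_imfs,
                      sd_threshold=cfg.sift_sd_threshold,
                      max_iters=cfg.sift_max_iters)
        try:
            imf_idx, peaks = select_optimal_imf(
                chunk, decomp, fs, cfg.smooth_cutoff_hz,
                cfg.envelope_peak_floor, cfg.bpm_max)
        except NoBeatsError:
            logger.warning("no beats in window starting at sample %d", s)
            continue
        # drop peaks next to the chunk edges (spline envelopes are distorted
        # there); the 1-s overlap lets the neighbouring window supply them
        guard = int(round(cfg.window_edge_guard_s * fs))
        lo = 0 if s == starts[0] else guard
        hi = chunk.size if s == starts[-1] else chunk.size - guard
        peaks = peaks[(peaks >= lo) & (peaks < hi)]
        if peaks.size == 0:
            continue
        window_peaks.append(peaks + s)
        window_starts.append(s)
        sources.append(imf_idx)
    if not window_peaks:
        return BeatSequence(np.array([], dtype=np.int64), fs)
    merged = stitch_windows(window_peaks, window_starts, win, overlap)
    gated = gate_physiological(merged, fs, cfg.bpm_min, cfg.bpm_max)
    seq = BeatSequence(gated, fs, source_imf=sources)
    return correct_ppis(seq)


# ---------------------------------------------------------------------------
# CWT envelope path
# ---------------------------------------------------------------------------

def _cgau2_kernel(scale: float, domain: float = 8.0) -> np.ndarray:
    """Order-2 complex Gaussian wavelet sampled at integer lags for one scale.

    psi(u) = C * d^2/du^2 [exp(-i u) exp(-u^2)] = C (4u^2 + 4iu - 3) exp(-u^2 - iu),
    normalised to unit continuous L2 energy; the returned kernel is
    ``psi(k/scale)/sqrt(scale)`` over ``|k| <= domain*scale``.
    """
    half = int(np.ceil(domain * scale))
    u = np.arange(-half, half + 1, dtype=np.float64) / scale
    psi = (4.0 * u**2 + 4.0j * u - 3.0) * np.exp(-(u**2) - 1.0j * u)
    energy = np.sum(np.abs(psi) ** 2) / scale  # discrete integral, du = 1/scale
    psi /= np.sqrt(energy)
    return psi / np.sqrt(scale)


def cwt_valve_band(signal: np.ndarray, fs: float, scale: float = 8.0,
                   window_s: float = 25.0) -> np.ndarray:
    """CWT magnitude at one scale of the order-2 complex Gaussian mother.

    Applied over consecutive 25-s windows (a shorter signal is one window) and
    concatenated; the chosen scale passes the sub-kHz band carrying fetal
    cardiac valve and wall motion.
    """
    x = np.asarray(signal, dtype=np.float64)
    kernel = _cgau2_kernel(scale)
    win = int(round(window_s * fs))
    if win <= 0 or x.size <= win:
        return np.abs(fftconvolve(x, np.conj(kernel[::-1]), mode="same"))
    out = np.empty(x.size, dtype=np.float64)
    for s in range(0, x.size, win):
        chunk = x[s:s + win]
        out[s:s + chunk.size] = np.abs(
            fftconvolve(chunk, np.conj(kernel[::-1]), mode="same"))
    return out


def cycle_envelopes(cwt_mag: np.ndarray, beats: BeatSequence,
                    smooth_cutoff_hz: float = 25.0) -> list[CycleEnvelope]:
    """Beat-aligned normalised cycle envelopes of the CWT magnitude.

    The envelope interpolates the local maxima of ``cwt_mag`` with a cubic
    spline, is smoothed with a zero-phase low-pass, cut at the beat locations,
    and each cycle is normalised to zero mean and unit SD. Zero-variance
    cycles are dropped.
    """
    env = _peak_envelope(cwt_mag)
    if env is None:
        env = cwt_mag.astype(np.float64)
    env = _smooth_lowpass(env, beats.fs, smooth_cutoff_hz)
    cycles: list[CycleEnvelope] = []
    b = beats.beat_samples
    for i in range(b.size - 1):
        seg = env[b[i]:b[i + 1]]
        if seg.size < 2:
            continue
        sd = float(np.std(seg))
        scale = float(np.max(np.abs(seg)))
        if sd <= 1e-10 * max(scale, 1.0):
            logger.warning("zero-variance cycle at sample %d dropped", int(b[i]))
            continue
        cycles.append(CycleEnvelope((seg - seg.mean()) / sd, int(b[i])))
    return cycles


def beats_to_csv(beats: BeatSequence, record_id: str, path) -> None:
    """Export beat annotations as CSV (record_id, beat_sample, ppi_samples)."""
    import pandas as pd

    ppis = np.concatenate([beats.ppis, [np.nan]]) if beats.n_beats else []
    pd.DataFrame({
        "record_id": record_id,
        "beat_sample": beats.beat_samples,
        "ppi_samples": ppis,
    }).to_csv(path, index=False)
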