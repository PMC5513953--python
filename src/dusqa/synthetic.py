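"""Seeded synthetic DUS-like recordings with known beats and quality labels.

The generator mimics the statistics of 1-D Doppler ultrasound audio of the
fetal heart at the 4 kHz working rate: a quasi-periodic train of cardiac
cycles (fetal heart rate ~110-180 bpm with Gaussian beat-to-beat variability),
each cycle carrying two Gaussian-windowed bursts of band-limited noise inside
the Doppler cardiac band (default 160-660 Hz) - a stronger systolic burst at
the beat location and a weaker diastolic burst ~42% through the cycle - plus
additive broadband noise at a controlled SNR and optional artifacts (dropouts
and low-frequency movement transients).

Every second gets a latent quality score (local SNR in dB, with a large
penalty for artifacts); three simulated annotators threshold it with
annotator-specific offsets, producing good/poor tracks whose consensus spans
all four quality classes at intermediate SNR. It is statistical mimicry only:
no physical insonation model, no maternal heart, no probe-angle dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from dusqa.signal_io import (
    AnnotationTrack,
    QualitySegment,
    Recording,
    assign_consensus_label,
    segment_recording,
)

logger = logging.getLogger(__name__)

# annotators share the latent per-second quality score but threshold it with
# these offsets (dB); the middle annotator is the reference
ANNOTATOR_OFFSETS_DB = (-1.5, 0.0, 1.5)
QUALITY_THRESHOLD_DB = 5.0  # latent SNR above which the reference annotator says good
ARTIFACT_PENALTY_DB = 60.0


@dataclass
class SynthSpec:
    """Stated world of one synthetic recording."""

    duration_s: float = 60.0
    fhr_bpm: float = 140.0
    fhr_sd_bpm: float = 5.0
    valve_band_hz: tuple[float, float] = (160.0, 660.0)
    n_bursts_per_cycle: int = 2
    snr_db: float = 10.0
    snr_db_per_second: np.ndarray | None = None  # overrides snr_db per second
    artifact_rate_per_min: float = 0.0
    fs: int = 4000
    seed: int = 0
    subject_id: str = "synth"
    record_id: str = "synth-0"

    def __post_init__(self) -> None:
        if not 90.0 <= self.fhr_bpm <= 210.0:
            raise ValueError("fhr_bpm must be within [90, 210]")
        if self.duration_s < 15.0:
            raise ValueError("duration_s must be >= 15 (template stages)")
        if self.n_bursts_per_cycle not in (1, 2):
            raise ValueError("n_bursts_per_cycle must be 1 or 2")
        lo, hi = self.valve_band_hz
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("valve_band_hz must lie inside (0, Nyquist)")


@dataclass
class GroundTruth:
    """What the generator planted: beats, annotator tracks, segment classes."""

    beat_samples: np.ndarray
    tracks: list[AnnotationTrack]
    latent_snr_db: np.ndarray
    artifact_seconds: np.ndarray
    class_per_segment: list[str] = field(default_factory=list)


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """White noise band-passed to the valve band (6th-order Butterworth)."""
    sos = butter(6, [band[0] / (fs / 2), band[1] / (fs / 2)],
                 btype="bandpass", output="sos")
    return sosfilt(sos, rng.standard_normal(n))


def _burst_window(t: np.ndarray, center: float, width_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width_s) ** 2)


def synth_recording(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate one recording at 4 kHz plus its ground truth.

    Beat locations (the systolic burst centres) are drawn with Gaussian
    beat-to-beat jitter around the mean heart rate. The same seed reproduces
    the output bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    n_seconds = int(np.floor(spec.duration_s))

    # --- beat train -------------------------------------------------------
    beats_s: list[float] = [0.2]
    while True:
        fhr_i = rng.normal(spec.fhr_bpm, spec.fhr_sd_bpm)
        fhr_i = float(np.clip(fhr_i, 90.0, 210.0))
        nxt = beats_s[-1] + 60.0 / fhr_i
        if nxt >= spec.duration_s - 0.05:
            break
        beats_s.append(nxt)
    beats_s = np.asarray(beats_s)
    beat_samples = np.round(beats_s * fs).astype(np.int64)
    ppis = np.diff(beats_s)

    # --- clean signal: modulated band-limited noise ------------------------
    carrier = _band_noise(n, fs, spec.valve_band_hz, rng)
    envelope = np.zeros(n)
    for k, b in enumerate(beats_s):
        cycle = ppis[k] if k < ppis.size else (60.0 / spec.fhr_bpm)
        envelope += _burst_window(t, b, 0.015)
        if spec.n_bursts_per_cycle == 2:
            envelope += 0.55 * _burst_window(t, b + 0.42 * cycle, 0.012)
    signal = carrier * envelope
    sig_power = float(np.mean(signal**2))
    if sig_power == 0.0:
        raise ValueError("degenerate spec produced a silent signal")

    # --- per-second SNR profile and additive broadband noise ---------------
    if spec.snr_db_per_second is not None:
        snr_profile = np.asarray(spec.snr_db_per_second, dtype=np.float64)
        if snr_profile.size != n_seconds:
            raise ValueError(
                f"snr_db_per_second must have {n_seconds} entries")
    else:
        snr_profile = np.full(n_seconds, float(spec.snr_db))
    noise = rng.standard_normal(n)
    noise_gain = np.empty(n)
    for s in range(n_seconds):
        target = sig_power / 10.0 ** (snr_profile[s] / 10.0)
        noise_gain[s * fs:(s + 1) * fs] = np.sqrt(target)
    if n_seconds * fs < n:
        noise_gain[n_seconds * fs:] = noise_gain[n_seconds * fs - 1]
    x = signal + noise * noise_gain

    # --- artifacts ----------------------------------------------------------
    artifact_seconds = np.zeros(n_seconds, dtype=bool)
    n_artifacts = rng.poisson(spec.artifact_rate_per_min * spec.duration_s / 60.0)
    for k in range(n_artifacts):
        start = float(rng.uniform(0.0, spec.duration_s - 1.0))
        dur = float(rng.uniform(0.3, 0.8))
        i0, i1 = int(start * fs), min(int((start + dur) * fs), n)
        if k % 2 == 0:  # dropout
            x[i0:i1] = 0.0
        else:  # movement transient: large low-frequency burst
            f_tr = rng.uniform(5.0, 30.0)
            amp = 6.0 * np.sqrt(sig_power)
            tt = t[i0:i1] - start
            x[i0:i1] += amp * np.sin(2 * np.pi * f_tr * tt) * np.hanning(i1 - i0)
        sec = np.arange(int(start), min(int(start + dur) + 1, n_seconds))
        artifact_seconds[sec] = True

    # --- latent quality and simulated annotators ----------------------------
    latent = snr_profile.copy()
    latent[artifact_seconds] -= ARTIFACT_PENALTY_DB
    tracks = [
        AnnotationTrack(f"annotator{j + 1}",
                        (latent >= QUALITY_THRESHOLD_DB + off).astype(int))
        for j, off in enumerate(ANNOTATOR_OFFSETS_DB)
    ]

    # keep int16-safe amplitude without altering SNR
    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x * (0.9 / peak)

    rec = Recording(x, float(fs), spec.subject_id, spec.record_id)
    truth = GroundTruth(beat_samples=beat_samples, tracks=tracks,
                        latent_snr_db=latent, artifact_seconds=artifact_seconds)
    return rec, truth


def label_segments(rec: Recording, truth: GroundTruth,
                   seg_len: float = 3.75, stride: float = 3.0) -> list[QualitySegment]:
    """Cut the recording and apply the consensus rule to the simulated tracks."""
    segments = segment_recording(rec, seg_len, stride)
    labelled = [assign_consensus_label(s, truth.tracks) for s in segments]
    truth.class_per_segment = [s.label.value for s in labelled]
    return labelled


def _block_snr_profile(n_seconds: int, block_s: int, good_db: float,
                       poor_db: float, poor_fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant per-second SNR alternating good/poor 15-s blocks."""
    n_blocks = int(np.ceil(n_seconds / block_s))
    n_poor = int(round(poor_fraction * n_blocks))
    kinds = np.array([False] * (n_blocks - n_poor) + [True] * n_poor)
    rng.shuffle(kinds)
    profile = np.empty(n_seconds)
    for b, is_poor in enumerate(kinds):
        profile[b * block_s:(b + 1) * block_s] = poor_db if is_poor else good_db
    return profile


def make_dataset(n_subjects: int = 10, records_per_subject: int = 1,
                 duration_s: float = 60.0, seed: int = 0,
                 fhr_range: tuple[float, float] = (120.0, 170.0),
                 good_snr_db: tuple[float, float] = (15.0, 25.0),
                 poor_snr_db: tuple[float, float] = (-12.0, -6.0),
                 poor_fraction: float = 0.5,
                 artifact_rate_per_min: float = 0.0,
                 block_s: int = 15
                 ) -> tuple[list[tuple[Recording, GroundTruth]], list[QualitySegment]]:
    """A labelled multi-subject segment set for end-to-end testing.

    Each record mixes good- and poor-SNR 15-s blocks (``poor_fraction`` of the
    record), so subjects contribute segments of several quality classes, as
    observed in real sessions. Per-subject heart rate and SNR levels are drawn
    from the stated ranges; consensus labels come from the simulated
    annotators through the same path as real annotations.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.SeedSequence([seed, 0x5D5])
    subject_seeds = root.spawn(n_subjects)
    recordings: list[tuple[Recording, GroundTruth]] = []
    segments: list[QualitySegment] = []
    for i in range(n_subjects):
        srng = np.random.default_rng(subject_seeds[i])
        fhr = float(srng.uniform(*fhr_range))
        good_db = float(srng.uniform(*good_snr_db))
        poor_db = float(srng.uniform(*poor_snr_db))
        for r in range(records_per_subject):
            n_seconds = int(np.floor(duration_s))
            profile = _block_snr_profile(n_seconds, block_s, good_db,
                                         poor_db, poor_fraction, srng)
            spec = SynthSpec(
                duration_s=duration_s,
                fhr_bpm=fhr,
                snr_db_per_second=profile,
                artifact_rate_per_min=artifact_rate_per_min,
                seed=int(srng.integers(2**31)),
                subject_id=f"S{i:02d}",
                record_id=f"S{i:02d}R{r:02d}",
            )
            rec, truth = synth_recording(spec)
            recordings.append((rec, truth))
            segments.extend(label_segments(rec, truth))
    return recordings, segments
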