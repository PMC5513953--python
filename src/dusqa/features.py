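"""Segment-level features: template SQIs, sample entropy, and PSD ratio.

Each 3.75-s segment is summarised by six numbers: the per-beat-median of the
four template-correlation SQIs, the sample entropy of the raw 4 kHz segment
(m = 2, tolerance 0.1 x SD), and the fraction of spectral power inside the
Doppler cardiac band (default 160-660 Hz). The discriminative band itself can
be re-derived by a grid search maximising the earth-mover's distance between
the PSD-ratio distributions of good and poor segments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.spatial import cKDTree
from scipy.stats import wasserstein_distance

from dusqa.beats import BeatSequence, cwt_valve_band, cycle_envelopes, detect_beats
from dusqa.config import PipelineConfig
from dusqa.signal_io import QualitySegment, QualityLabel, Recording, segment_recording
from dusqa.template_sqi import build_templates, score_beats, segment_sqis

logger = logging.getLogger(__name__)

FEATURE_ORDER = ("sqi1", "sqi2", "sqi3", "sqi4", "h_s", "psd_ratio")


@dataclass
class FeatureVector:
    """The six per-segment features plus identity and label."""

    sqi1: float
    sqi2: float
    sqi3: float
    sqi4: float
    h_s: float
    psd_ratio: float
    label: QualityLabel = QualityLabel.UNLABELED
    subject_id: str = ""
    record_id: str = ""
    start_s: float = 0.0

    def values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_ORDER])


def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Matched-pair counts (A, B) for template lengths m+1 and m.

    Templates are ``x[i:i+m]`` for i = 0..N-m-1 (the last length-m window is
    dropped so the m- and (m+1)-length template sets share indices); matching
    is Chebyshev distance <= r over unordered pairs i < j (no self-matches).
    """
    n = x.size
    n_templates = n - m  # i = 0 .. n-m-1
    Xm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    Xm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    tree_m = cKDTree(Xm)
    tree_m1 = cKDTree(Xm1)
    b_pairs = (tree_m.count_neighbors(tree_m, r, p=np.inf) - n_templates) // 2
    a_pairs = (tree_m1.count_neighbors(tree_m1, r, p=np.inf) - Xm1.shape[0]) // 2
    return int(a_pairs), int(b_pairs)


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.1,
                   return_counts: bool = False):
    """Sample entropy ``-ln(A/B)`` with tolerance ``r = r_frac * SD(x)``.

    B counts template pairs of length m within Chebyshev distance r
    (self-matches excluded), A likewise for length m+1. A constant input
    returns the degenerate sentinel 0; A = 0 is capped at
    ``ln(B * (N - m - 1))`` to keep the statistic finite.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {n}")
    sd = float(np.std(x))
    if sd == 0.0:
        logger.warning("sample_entropy: zero-variance input, sentinel 0 returned")
        return (0.0, 0, 0) if return_counts else 0.0
    r = r_frac * sd
    a, b = _sampen_counts(x, m, r)
    if b == 0:
        h = 0.0
    elif a == 0:
        h = math.log(b * (n - m - 1))
    else:
        h = -math.log(a / b)
    return (h, a, b) if return_counts else h


def psd_ratio(samples: np.ndarray, fs: float = 4000.0,
              band: tuple[float, float] = (160.0, 660.0),
              welch_window_s: float = 1.0, welch_overlap: float = 0.5) -> float:
    """Fraction of spectral power inside ``band`` (relative to 0-Nyquist).

    Spectrum estimated by Welch's averaged periodogram with Hann-tapered 1-s
    windows at 50% overlap; DC is excluded from both numerator and
    denominator. A zero-power segment returns 0.
    """
    x = np.asarray(samples, dtype=np.float64)
    nperseg = min(int(round(welch_window_s * fs)), x.size)
    noverlap = int(round(welch_overlap * nperseg))
    f, pxx = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    pxx = pxx[f > 0]
    f = f[f > 0]
    total = float(np.sum(pxx))
    if total == 0.0:
        logger.warning("psd_ratio: zero-power segment")
        return 0.0
    in_band = (f >= band[0]) & (f <= band[1])
    return float(np.sum(pxx[in_band]) / total)


def earth_movers_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1-D Wasserstein-1 distance between two empirical sample sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    return float(wasserstein_distance(a, b))


def optimize_band(good_segments: Sequence[np.ndarray],
                  poor_segments: Sequence[np.ndarray], fs: float = 4000.0,
                  lo_grid: tuple[float, float] = (80.0, 400.0),
                  hi_grid: tuple[float, float] = (580.0, 900.0),
                  step: float = 20.0) -> tuple[float, float]:
    """Grid-search the PSD band separating good from poor segments.

    For each candidate (lo, hi), the earth-mover's distance between the two
    classes' PSD-ratio distributions is computed; the argmax wins, ties going
    to the widest band (then the lowest lower edge).
    """
    if len(good_segments) < 2 or len(poor_segments) < 2:
        raise ValueError("need at least 2 segments per class")
    los = np.arange(lo_grid[0], lo_grid[1] + 1e-9, step)
    his = np.arange(hi_grid[0], hi_grid[1] + 1e-9, step)
    if los.size == 0 or his.size == 0:
        raise ValueError("empty band grid")
    best = None
    for lo, hi in itertools.product(los, his):
        g = np.array([psd_ratio(s, fs, (lo, hi)) for s in good_segments])
        p = np.array([psd_ratio(s, fs, (lo, hi)) for s in poor_segments])
        dist = earth_movers_distance(g, p)
        key = (dist, hi - lo, -lo)
        if best is None or key > best[0]:
            best = (key, (float(lo), float(hi)))
    return best[1]


def build_feature_vector(segment: QualitySegment, beat_sqis,
                         cfg: PipelineConfig | None = None) -> FeatureVector:
    """Assemble the 6-feature vector of one segment.

    Segment SQIs are per-beat medians (0 when the segment holds no beats);
    sample entropy and the PSD ratio are computed on the raw 4 kHz samples
    regardless.
    """
    cfg = cfg or PipelineConfig()
    fs = cfg.working_fs
    i0 = int(round(segment.start_time * fs))
    i1 = i0 + int(round(segment.duration * fs))
    s1, s2, s3, s4 = segment_sqis(i0, i1, beat_sqis)
    return FeatureVector(
        sqi1=s1, sqi2=s2, sqi3=s3, sqi4=s4,
        h_s=sample_entropy(segment.samples, cfg.sampen_m, cfg.sampen_r_frac),
        psd_ratio=psd_ratio(segment.samples, fs, cfg.psd_band_hz,
                            cfg.welch_window_s, cfg.welch_overlap),
        label=segment.label,
        subject_id=segment.subject_id,
        record_id=segment.record_id,
        start_s=segment.start_time,
    )


def extract_features(rec: Recording, cfg: PipelineConfig | None = None,
                     segments: Sequence[QualitySegment] | None = None
                     ) -> tuple[list[FeatureVector], BeatSequence]:
    """Run the full per-record pipeline and return per-segment feature vectors.

    The recording must already be at the working rate. ``segments`` may carry
    consensus labels; when omitted, unlabeled segments are cut here.
    """
    cfg = cfg or PipelineConfig()
    fs = cfg.working_fs
    if rec.fs != fs:
        raise ValueError(f"recording must be at {fs} Hz (got {rec.fs}); resample first")
    if segments is None:
        segments = segment_recording(rec, cfg.segment_len_s, cfg.segment_stride_s)
    beats = detect_beats(rec.samples, fs, cfg)
    if beats.n_beats >= 2:
        mag = cwt_valve_band(rec.samples, fs, cfg.cwt_scale, cfg.cwt_window_s)
        cycles = cycle_envelopes(mag, beats, cfg.smooth_cutoff_hz)
        n_windows = rec.samples.size // int(round(cfg.template_window_s * fs)) + 1
        templates = build_templates(cycles, fs, cfg.template_window_s,
                                    cfg.template_corr_threshold,
                                    cfg.template_validity_fraction, n_windows)
        beat_sqis = score_beats(cycles, templates, fs, cfg.template_window_s, cfg.wdtw_g)
    else:
        logger.warning("record %s: fewer than 2 beats detected; SQIs are 0", rec.record_id)
        beat_sqis = []
    return [build_feature_vector(s, beat_sqis, cfg) for s in segments], beats


def features_to_frame(fvs: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature matrix with identity columns, one row per segment."""
    return pd.DataFrame([
        {"subject_id": fv.subject_id, "record_id": fv.record_id,
         "start_s": fv.start_s,
         **{name: getattr(fv, name) for name in FEATURE_ORDER},
         "label": fv.label.value}
        for fv in fvs
    ])
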