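"""Recording and annotation I/O, resampling, and segment selection.

Recordings are mono WAV audio (nominally 44.1 kHz, ~1 min). Quality
annotations are per-second binary labels (1 = good, 0 = poor) from several
independent annotators, stored as CSV with columns
``second_index, annotator_id, label``.

The working representation is 4 kHz audio cut into 3.75-s segments on a 3-s
stride; a segment keeps a consensus quality class only when every annotator is
internally consistent over its span (good / mostly_clean / mostly_noisy / poor
for 3/2/1/0 good votes, otherwise rejected).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import firls, resample_poly

logger = logging.getLogger(__name__)


class QualityLabel(str, Enum):
    GOOD = "good"
    MOSTLY_CLEAN = "mostly_clean"
    MOSTLY_NOISY = "mostly_noisy"
    POOR = "poor"
    REJECTED = "rejected"
    UNLABELED = "unlabeled"


_VOTES_TO_LABEL = {
    3: QualityLabel.GOOD,
    2: QualityLabel.MOSTLY_CLEAN,
    1: QualityLabel.MOSTLY_NOISY,
    0: QualityLabel.POOR,
}


@dataclass
class Recording:
    """A mono DUS waveform with sampling rate and subject identity."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class AnnotationTrack:
    """Per-second binary quality labels (1 = good, 0 = poor) of one annotator."""

    annotator_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = poor, 1 = good)")


@dataclass
class QualitySegment:
    """A 3.75-s excerpt at 4 kHz with its consensus quality class."""

    samples: np.ndarray
    start_time: float
    duration: float = 3.75
    label: QualityLabel = QualityLabel.UNLABELED
    subject_id: str = ""
    record_id: str = ""


def load_recording(path: str | Path, subject_id: str = "", record_id: str = "") -> Recording:
    """Read a mono WAV file (PCM16/PCM32 or float) into a :class:`Recording`.

    Integer PCM is scaled to [-1, 1). Multi-channel files are rejected.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"{path}: multi-channel WAV not supported ({data.shape[1]} channels)")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    rid = record_id or path.stem
    return Recording(samples=data, fs=float(fs), subject_id=subject_id, record_id=rid)


def save_recording(rec: Recording, path: str | Path, dtype: str = "int16") -> None:
    """Write a recording as a mono WAV file (PCM 16-bit by default)."""
    if dtype == "int16":
        clipped = np.clip(rec.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif dtype == "float32":
        data = rec.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    wavfile.write(Path(path), int(rec.fs), data)


def _antialias_fir(fs_in: float, target_fs: float, n_taps: int,
                   cutoff_frac: float) -> np.ndarray:
    """Least-squares linear-phase low-pass anti-aliasing FIR.

    Designed at the input rate: passband up to ``cutoff_frac`` of the target
    Nyquist, stopband from the target Nyquist upward.
    """
    nyq_in = fs_in / 2.0
    f_pass = cutoff_frac * (target_fs / 2.0) / nyq_in
    f_stop = min(1.0, (target_fs / 2.0) / nyq_in)
    if f_stop - f_pass < 1e-6:
        f_stop = min(1.0, f_pass + 0.01)
    if n_taps % 2 == 0:
        n_taps += 1  # firls needs an odd tap count (type-I linear phase)
    return firls(n_taps, [0.0, f_pass, f_stop, 1.0], [1.0, 1.0, 0.0, 0.0])


def resample_to_working_rate(rec: Recording, target_fs: int = 4000,
                             filter_order: int = 512,
                             cutoff_frac: float = 0.9) -> Recording:
    """Downsample a recording to the working rate (default 4 kHz).

    Anti-aliases with a least-squares linear-phase FIR at the input rate
    (applied as a centred, zero-net-delay convolution), then resamples by the
    rational factor. Upsampling is not supported.
    """
    if rec.fs < target_fs:
        raise ValueError(f"upsampling not supported (fs={rec.fs} < target {target_fs})")
    if rec.fs == target_fs:
        return Recording(rec.samples.copy(), float(target_fs), rec.subject_id, rec.record_id)
    frac = Fraction(int(round(target_fs)), int(round(rec.fs)))
    up, down = frac.numerator, frac.denominator
    taps = _antialias_fir(rec.fs, target_fs, filter_order + 1, cutoff_frac)
    filtered = np.convolve(rec.samples, taps, mode="same")
    out = resample_poly(filtered, up, down)
    n_expected = int(round(rec.samples.size * target_fs / rec.fs))
    if out.size > n_expected:
        out = out[:n_expected]
    elif out.size < n_expected:
        out = np.pad(out, (0, n_expected - out.size))
    return Recording(out, float(target_fs), rec.subject_id, rec.record_id)


def segment_recording(rec: Recording, seg_len: float = 3.75,
                      stride: float = 3.0) -> list[QualitySegment]:
    """Cut a 4 kHz recording into fixed-length overlapping segments.

    Segments start at 0, stride, 2*stride, ...; the count is
    ``floor((duration - seg_len)/stride) + 1``. Each segment holds exactly
    ``seg_len * fs`` samples (15000 at the defaults).
    """
    fs = rec.fs
    duration = rec.duration_s
    n_samp = int(round(seg_len * fs))
    if duration < seg_len:
        logger.warning("record %s shorter than one segment (%.2f s < %.2f s)",
                       rec.record_id, duration, seg_len)
        return []
    n_segments = int(math.floor((duration - seg_len) / stride + 1e-9)) + 1
    out = []
    for k in range(n_segments):
        start_t = k * stride
        i0 = int(round(start_t * fs))
        out.append(QualitySegment(
            samples=rec.samples[i0:i0 + n_samp],
            start_time=start_t,
            duration=seg_len,
            subject_id=rec.subject_id,
            record_id=rec.record_id,
        ))
    return out


def assign_consensus_label(segment: QualitySegment,
                           tracks: Sequence[AnnotationTrack]) -> QualitySegment:
    """Assign the 4-class consensus label from three per-second annotations.

    A segment spans whole seconds ``floor(start)`` through
    ``floor(start + duration - eps)``; the trailing partial second inherits the
    label of the second containing it. If any annotator's labels over that span
    are not all identical the segment is rejected; otherwise the number of
    annotators voting good maps 3/2/1/0 to
    good / mostly_clean / mostly_noisy / poor.
    """
    if len(tracks) != 3:
        raise ValueError(f"exactly 3 annotation tracks required, got {len(tracks)}")
    first = int(math.floor(segment.start_time + 1e-9))
    last = int(math.floor(segment.start_time + segment.duration - 1e-9))
    votes = 0
    for track in tracks:
        if last >= track.labels.size:
            raise ValueError(
                f"annotator {track.annotator_id}: no labels for seconds "
                f"{first}..{last} (track has {track.labels.size})")
        span = track.labels[first:last + 1]
        if not (span == span[0]).all():
            segment.label = QualityLabel.REJECTED
            return segment
        votes += int(span[0])
    segment.label = _VOTES_TO_LABEL[votes]
    return segment


def load_annotations(path: str | Path) -> list[AnnotationTrack]:
    """Read per-second annotations from CSV (second_index, annotator_id, label)."""
    df = pd.read_csv(path)
    required = {"second_index", "annotator_id", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    tracks = []
    for aid, grp in df.groupby("annotator_id", sort=True):
        grp = grp.sort_values("second_index")
        n = int(grp["second_index"].max()) + 1
        if not (grp["second_index"].to_numpy() == np.arange(n)).all():
            raise ValueError(f"annotator {aid}: second indices must be 0..{n - 1} contiguous")
        labels = grp["label"].map({"good": 1, "poor": 0, 1: 1, 0: 0}).to_numpy()
        if np.isnan(labels.astype(float)).any():
            raise ValueError(f"annotator {aid}: labels must be 'good'/'poor' or 1/0")
        tracks.append(AnnotationTrack(str(aid), labels.astype(int)))
    return tracks


def save_annotations(tracks: Sequence[AnnotationTrack], path: str | Path) -> None:
    rows = [
        {"second_index": i, "annotator_id": t.annotator_id,
         "label": "good" if v else "poor"}
        for t in tracks for i, v in enumerate(t.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def segments_index(segments: Iterable[QualitySegment]) -> pd.DataFrame:
    """Tabulate segments as (record_id, start_s, label) for export."""
    return pd.DataFrame(
        [{"record_id": s.record_id, "start_s": s.start_time, "label": s.label.value}
         for s in segments]
    )
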