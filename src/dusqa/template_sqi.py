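"""Running envelope templates and the four template-correlation SQIs.

Each recording is tiled into 15-s windows. A window's template is the
pointwise mean of its beat-aligned cycle envelopes, with length L equal to the
rounded mean beat-to-beat interval of the window. Templates are refined by
re-averaging only cycles correlating r >= 0.6 with the initial template; a
window where fewer than 20% of cycles reach that gate is invalid and borrows
the previous (else next) window's template.

Per beat, four signal-quality indices are the Pearson correlations of the
cycle envelope with its window template after four time-normalisation schemes:
SQI1 truncation/zero-padding to L, SQI2 linear resampling to L, SQI3 DTW
alignment to L, SQI4 weighted DTW with a logistic phase penalty. Negative
correlations are clipped to zero, so every SQI lies in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from dusqa.beats import BeatSequence, CycleEnvelope

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@dataclass
class Template:
    """Envelope prototype of one 15-s window."""

    values: np.ndarray
    L: int
    window_index: int
    valid: bool = True
    support_count: int = 0

    @classmethod
    def invalid(cls, window_index: int, L: int = 2) -> "Template":
        return cls(values=np.zeros(max(L, 2)), L=max(L, 2),
                   window_index=window_index, valid=False, support_count=0)


@dataclass
class BeatSQI:
    """Four quality indices of one beat against its window template."""

    sqi1: float
    sqi2: float
    sqi3: float
    sqi4: float
    beat_index: int
    window_index: int
    onset_sample: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0.0 when either vector has zero variance."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _clip01(r: float) -> float:
    return float(min(max(r, 0.0), 1.0))


def _fit_length(x: np.ndarray, L: int) -> np.ndarray:
    """Truncate to L or zero-pad at the tail (cycles are onset-aligned)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size >= L:
        return x[:L]
    return np.pad(x, (0, L - x.size))


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def initial_template(cycles: Sequence[CycleEnvelope], window_index: int = 0) -> Template:
    """Average the window's cycles into a length-L prototype.

    L is the rounded mean beat-to-beat interval (cycle length) of the window;
    cycles are truncated or tail-zero-padded to L before pointwise averaging.
    Fewer than two cycles yield an invalid template.
    """
    if len(cycles) < 2:
        return Template.invalid(window_index)
    L = int(round(float(np.mean([c.length_samples for c in cycles]))))
    L = max(L, 2)
    stack = np.stack([_fit_length(c.values, L) for c in cycles])
    return Template(values=stack.mean(axis=0), L=L, window_index=window_index,
                    valid=True, support_count=len(cycles))


def update_template(t: Template, cycles: Sequence[CycleEnvelope],
                    neighbors: tuple[Template | None, Template | None] = (None, None),
                    corr_threshold: float = 0.6,
                    validity_fraction: float = 0.2) -> Template:
    """Correlation-gated template refinement with neighbour fallback.

    Cycles (fitted to L) correlating ``r >= corr_threshold`` with the initial
    template are re-averaged into the updated template, provided they make up
    at least ``validity_fraction`` of the window's cycles. Otherwise the
    template is invalid and the previous window's template is used; if that is
    also invalid, the next window's. Both neighbours invalid leaves the window
    template-less (its beats score 0).
    """
    prev_t, next_t = neighbors
    if not t.valid or not cycles:
        return _fallback(t.window_index, prev_t, next_t, t.L)
    fitted = [_fit_length(c.values, t.L) for c in cycles]
    corrs = np.array([_pearson(f, t.values) for f in fitted])
    selected = corrs >= corr_threshold
    if selected.sum() >= validity_fraction * len(cycles) and selected.any():
        values = np.stack([f for f, s in zip(fitted, selected) if s]).mean(axis=0)
        return Template(values=values, L=t.L, window_index=t.window_index,
                        valid=True, support_count=int(selected.sum()))
    return _fallback(t.window_index, prev_t, next_t, t.L)


def _fallback(window_index: int, prev_t: Template | None,
              next_t: Template | None, L: int) -> Template:
    for nb in (prev_t, next_t):
        if nb is not None and nb.valid:
            return Template(values=nb.values.copy(), L=nb.L,
                            window_index=window_index, valid=True,
                            support_count=nb.support_count)
    logger.warning("window %d has no usable template; its beats score 0", window_index)
    return Template.invalid(window_index, L)


def build_templates(cycles: Sequence[CycleEnvelope], fs: float,
                    window_s: float = 15.0, corr_threshold: float = 0.6,
                    validity_fraction: float = 0.2,
                    n_windows: int | None = None) -> list[Template]:
    """Initial + updated templates for the contiguous 15-s windows of a record.

    Windows tile from t = 0; a cycle belongs to the window containing its
    onset. The update pass runs on all initial templates first, then invalid
    windows borrow the previous (else next) window's updated template, so the
    fallback does not depend on processing order.
    """
    win = int(round(window_s * fs))
    if n_windows is None:
        last = max((c.onset_sample for c in cycles), default=0)
        n_windows = last // win + 1
    grouped: list[list[CycleEnvelope]] = [[] for _ in range(n_windows)]
    for c in cycles:
        w = c.onset_sample // win
        if w < n_windows:
            grouped[w].append(c)
    initials = [initial_template(g, w) for w, g in enumerate(grouped)]
    # first pass: gate/update without fallback
    updated: list[Template] = []
    for t, g in zip(initials, grouped):
        updated.append(update_template(t, g, (None, None),
                                       corr_threshold, validity_fraction))
    # second pass: resolve invalid windows from neighbours
    final: list[Template] = []
    for w, t in enumerate(updated):
        if t.valid:
            final.append(t)
            continue
        prev_t = updated[w - 1] if w > 0 else None
        next_t = updated[w + 1] if w + 1 < len(updated) else None
        final.append(_fallback(w, prev_t, next_t, t.L))
    return final


# ---------------------------------------------------------------------------
# DTW alignment
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_dp(seq: np.ndarray, ref: np.ndarray, w: np.ndarray):  # pragma: no cover
    n, m = seq.size, ref.size
    D = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            d = abs(i - j)
            c = w[d] * (seq[i] - ref[j]) ** 2
            if i == 0 and j == 0:
                D[i, j] = c
            else:
                best = np.inf
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                D[i, j] = c + best
    # backtrack (prefer diagonal on ties)
    path_i = np.empty(n + m, dtype=np.int64)
    path_j = np.empty(n + m, dtype=np.int64)
    k = n + m - 1
    i, j = n - 1, m - 1
    path_i[k] = i
    path_j[k] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        k -= 1
        path_i[k] = i
        path_j[k] = j
    return D[n - 1, m - 1], path_i[k:], path_j[k:]


def dtw_cost_and_path(seq: np.ndarray, ref: np.ndarray,
                      weights: Callable[[np.ndarray], np.ndarray] | None = None
                      ) -> tuple[float, list[tuple[int, int]]]:
    """DP cost and an optimal warping path.

    Minimises ``sum w(|i-j|) * (seq[i]-ref[j])^2`` over monotone, continuous,
    boundary-anchored paths with steps {(1,0), (0,1), (1,1)}; ``weights`` maps
    absolute phase lag to a non-negative weight (uniform 1 when omitted).
    """
    seq = np.asarray(seq, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if seq.size < 2 or ref.size < 2:
        raise ValueError("both sequences need length >= 2")
    lags = np.arange(max(seq.size, ref.size), dtype=np.float64)
    w = np.ones_like(lags) if weights is None else np.asarray(weights(lags), dtype=np.float64)
    cost, pi, pj = _dtw_dp(seq, ref, w)
    return float(cost), list(zip(pi.tolist(), pj.tolist()))


def dtw_align(seq: np.ndarray, ref: np.ndarray,
              weights: Callable[[np.ndarray], np.ndarray] | None = None) -> np.ndarray:
    """Warp ``seq`` onto the time base of ``ref``.

    The aligned value at each reference index is the mean of the sequence
    samples matched to it along the optimal path; output length = len(ref).
    """
    seq = np.asarray(seq, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    _, path = dtw_cost_and_path(seq, ref, weights)
    sums = np.zeros(ref.size)
    counts = np.zeros(ref.size)
    for i, j in path:
        sums[j] += seq[i]
        counts[j] += 1
    return sums / counts


def logistic_weight(L: int, g: float) -> Callable[[np.ndarray], np.ndarray]:
    """Modified logistic phase-penalty weight, midpoint L/2, steepness g."""
    def w(d: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-g * (np.asarray(d, dtype=np.float64) - L / 2.0)))
    return w


# ---------------------------------------------------------------------------
# The four SQIs
# ---------------------------------------------------------------------------

def sqi1_direct(cycle: CycleEnvelope, t: Template) -> float:
    """Direct matching: truncate/zero-pad the cycle to L, correlate, clip at 0."""
    if not t.valid:
        return 0.0
    return _clip01(_pearson(_fit_length(cycle.values, t.L), t.values))


def sqi2_linear(cycle: CycleEnvelope, t: Template) -> float:
    """Linear resampling: stretch/compress the full cycle to L points, correlate."""
    if not t.valid or cycle.length_samples < 2:
        return 0.0
    x = cycle.values
    resampled = np.interp(np.linspace(0.0, 1.0, t.L),
                          np.linspace(0.0, 1.0, x.size), x)
    return _clip01(_pearson(resampled, t.values))


def sqi3_dtw(cycle: CycleEnvelope, t: Template) -> float:
    """DTW alignment to L with uniform weights, then correlation."""
    if not t.valid or cycle.length_samples < 2:
        return 0.0
    return _clip01(_pearson(dtw_align(cycle.values, t.values), t.values))


def sqi4_wdtw(cycle: CycleEnvelope, t: Template, g: float = 0.02) -> float:
    """Weighted DTW: logistic phase penalty (steepness g) discourages large warps."""
    if not t.valid or cycle.length_samples < 2:
        return 0.0
    aligned = dtw_align(cycle.values, t.values, logistic_weight(t.L, g))
    return _clip01(_pearson(aligned, t.values))


def score_beats(cycles: Sequence[CycleEnvelope], templates: Sequence[Template],
                fs: float, window_s: float = 15.0, g: float = 0.02) -> list[BeatSQI]:
    """All four SQIs for every cycle against its own window's template."""
    win = int(round(window_s * fs))
    out: list[BeatSQI] = []
    for k, c in enumerate(cycles):
        w = min(c.onset_sample // win, len(templates) - 1) if templates else 0
        t = templates[w] if templates else Template.invalid(0)
        out.append(BeatSQI(
            sqi1=sqi1_direct(c, t),
            sqi2=sqi2_linear(c, t),
            sqi3=sqi3_dtw(c, t),
            sqi4=sqi4_wdtw(c, t, g),
            beat_index=k,
            window_index=w,
            onset_sample=c.onset_sample,
        ))
    return out


def segment_sqis(start_sample: int, end_sample: int,
                 beat_sqis: Sequence[BeatSQI]) -> tuple[float, float, float, float]:
    """Median per-index SQI over the beats whose onset falls in a segment.

    A segment without beats scores 0 on all four indices.
    """
    in_seg = [b for b in beat_sqis if start_sample <= b.onset_sample < end_sample]
    if not in_seg:
        logger.debug("no beats in segment [%d, %d); SQIs set to 0",
                     start_sample, end_sample)
        return 0.0, 0.0, 0.0, 0.0
    return (
        float(np.median([b.sqi1 for b in in_seg])),
        float(np.median([b.sqi2 for b in in_seg])),
        float(np.median([b.sqi3 for b in in_seg])),
        float(np.median([b.sqi4 for b in in_seg])),
    )


def beat_sqis_to_csv(beat_sqis: Sequence[BeatSQI], record_id: str, path) -> None:
    """Per-beat SQI table: record_id, beat_sample, window_index, sqi1..sqi4."""
    import pandas as pd

    pd.DataFrame([
        {"record_id": record_id, "beat_sample": b.onset_sample,
         "window_index": b.window_index, "sqi1": b.sqi1, "sqi2": b.sqi2,
         "sqi3": b.sqi3, "sqi4": b.sqi4}
        for b in beat_sqis
    ]).to_csv(path, index=False)
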