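"""Empirical mode decomposition (EMD) via the classical sifting procedure.

EMD decomposes a non-stationary signal into intrinsic mode functions (IMFs),
ordered from highest to lowest characteristic frequency, plus a residual.
An IMF (i) has extrema and zero-crossing counts differing by at most one and
(ii) has a local mean (average of the upper and lower spline envelopes) near
zero everywhere. Sifting iteratively subtracts the envelope mean until the
candidate satisfies a Cauchy-type convergence criterion; decomposition stops
when the residual is monotonic or has too few extrema to envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residual; ``sum(imfs) + residual`` equals the input."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    n_sift_iters: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateaus collapse to one extremum)."""
    d = np.diff(x)
    s = np.sign(d)
    # propagate the previous non-zero slope through plateaus
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0)
    change = np.diff(filled)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int,
                   n_mirror: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mirror the nearest extrema about both signal ends for spline anchoring."""
    left_i = -idx[1:n_mirror + 1][::-1] if idx[0] == 0 else -idx[:n_mirror][::-1]
    left_v = val[1:n_mirror + 1][::-1] if idx[0] == 0 else val[:n_mirror][::-1]
    last = n - 1
    if idx[-1] == last:
        right_i = 2 * last - idx[-n_mirror - 1:-1][::-1]
        right_v = val[-n_mirror - 1:-1][::-1]
    else:
        right_i = 2 * last - idx[-n_mirror:][::-1]
        right_v = val[-n_mirror:][::-1]
    return (np.concatenate([left_i, idx, right_i]),
            np.concatenate([left_v, val, right_v]))


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    ext_i, ext_v = _mirror_extend(idx, x[idx], x.size)
    ext_i, uniq = np.unique(ext_i, return_index=True)
    spline = CubicSpline(ext_i, ext_v[uniq])
    return spline(np.arange(x.size))


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper/lower spline envelopes, or None if not enveloppable."""
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    return 0.5 * (_envelope(x, maxima) + _envelope(x, minima))


def _is_monotonic(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def sift(signal: np.ndarray, max_imfs: int = 4, sd_threshold: float = 0.2,
         max_iters: int = 100) -> IMFDecomposition:
    """Decompose a signal into up to ``max_imfs`` IMFs plus a residual.

    Per-IMF sifting stops when the Cauchy criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold`` is met (or after
    ``max_iters`` iterations). The decomposition stops early when the residual
    is monotonic or has fewer than four extrema (spline envelopes undefined).

    A constant or monotonic input yields zero IMFs with ``residual == input``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("signal must be 1-D with at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    residual = x.copy()
    imfs: list[np.ndarray] = []
    iters: list[int] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if _is_monotonic(residual) or maxima.size + minima.size < 4:
            break
        h = residual.copy()
        n_it = 0
        for n_it in range(1, max_iters + 1):
            mean_env = _envelope_mean(h)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                # also require the defining count property (Huang's criterion):
                # extrema and zero crossings may differ by at most one
                maxima, minima = _local_extrema(h)
                if abs(int(maxima.size + minima.size) - _count_zero_crossings(h)) <= 1:
                    break
        imfs.append(h)
        iters.append(n_it)
        residual = residual - h
    return IMFDecomposition(imfs=imfs, residual=residual, n_sift_iters=iters)


def imf_property_check(x: np.ndarray, mean_tol_frac: float = 0.05,
                       boundary_slack: int = 0) -> tuple[int, int, bool]:
    """Check the defining IMF properties of a sequence.

    Returns ``(n_extrema, n_zero_crossings, ok)`` where ``ok`` requires
    ``|n_extrema - n_zero_crossings| <= 1 + boundary_slack`` and, when the
    sequence can be enveloped, a local envelope mean whose maximum magnitude is
    below ``mean_tol_frac`` times the signal SD.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = _local_extrema(x)
    n_extrema = int(maxima.size + minima.size)
    n_zc = _count_zero_crossings(x)
    ok = abs(n_extrema - n_zc) <= 1 + boundary_slack
    if ok:
        mean_env = _envelope_mean(x)
        sd = float(np.std(x))
        if mean_env is not None and sd > 0:
            ok = bool(np.max(np.abs(mean_env)) < mean_tol_frac * sd)
    return n_extrema, n_zc, ok


def dump_imfs_csv(decomp: IMFDecomposition, path) -> None:
    """Debug export of a decomposition (one column per IMF plus residual)."""
    import pandas as pd

    cols = {f"imf{i + 1}": imf for i, imf in enumerate(decomp.imfs)}
    cols["residual"] = decomp.residual
    pd.DataFrame(cols).to_csv(path, index=False)
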