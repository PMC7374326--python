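"""Empirical mode decomposition with extrema halving.

Canonical sifting (cubic-spline envelopes of local extrema, mean-envelope
subtraction) with two deltas relative to textbook EMD:

* only every other maximum/minimum is used when building the envelopes
  (``halve_extrema``), trading envelope fidelity for speed;
* sifting for one IMF stops when the normalized squared difference between
  successive mean envelopes,

      sum_n |m_{t-1}[n] - m_t[n]|^2 / m_{t-1}[n]^2,

  drops below ``stop_threshold`` (terms with |m_{t-1}| < 1e-12 skipped),
  or the iteration count reaches N/2.

The residue is computed as ``signal - sum(imfs)`` so the reconstruction
identity holds to floating-point precision by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import DataError

_DIV_GUARD = 1e-12


@dataclass
class SiftConfig:
    max_imfs: int = 5
    stop_threshold: float = 0.2
    halve_extrema: bool = True
    halve_each_pass: bool = True
    interpolation: str = "cubic_spline"
    # practical per-IMF cap; the theoretical bound N/2 still applies on top
    max_sift_iterations: int = 8

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise DataError("max_imfs must be >= 1")
        if self.max_sift_iterations < 1:
            raise DataError("max_sift_iterations must be >= 1")
        if self.stop_threshold <= 0:
            raise DataError("stop_threshold must be > 0")
        if self.interpolation != "cubic_spline":
            raise DataError(f"unsupported interpolation {self.interpolation!r}")


@dataclass
class IMFSet:
    """Intrinsic mode functions + residue of one channel signal."""

    source_length: int
    imfs: list[np.ndarray]
    residue: np.ndarray
    n_sift_iterations: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residue) != self.source_length:
            raise DataError("residue length must equal source_length")
        for imf in self.imfs:
            if len(imf) != self.source_length:
                raise DataError("every IMF must have source_length samples")


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateaus take the midpoint.

    Monotone signals yield two empty arrays.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise DataError("find_extrema requires length >= 3")
    # run-length compress equal neighbours so plateaus act as single points
    keep = np.concatenate(([True], np.diff(x) != 0))
    starts = np.flatnonzero(keep)
    vals = x[starts]
    if vals.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(np.diff(vals))
    turns = np.diff(s)
    max_runs = np.flatnonzero(turns < 0) + 1
    min_runs = np.flatnonzero(turns > 0) + 1
    ends = np.append(starts[1:], x.size) - 1
    maxima = (starts[max_runs] + ends[max_runs]) // 2
    minima = (starts[min_runs] + ends[min_runs]) // 2
    return maxima.astype(int), minima.astype(int)


def halve_extrema(
    maxima: np.ndarray, minima: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep every other extremum per list, starting at the first."""
    return np.asarray(maxima)[::2], np.asarray(minima)[::2]


def _envelope(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through (idx, values) with mirrored end padding."""
    t = idx.astype(float)
    v = values.astype(float)
    # mirror up to two extrema about each end of the signal
    left_t, left_v, right_t, right_v = [], [], [], []
    for j in range(min(2, t.size)):
        lt = -t[j]
        if lt < (left_t[-1] if left_t else t[0]):
            left_t.append(lt)
            left_v.append(v[j])
        rt = 2.0 * (n - 1) - t[-1 - j]
        if rt > (right_t[-1] if right_t else t[-1]):
            right_t.append(rt)
            right_v.append(v[-1 - j])
    tt = np.concatenate((left_t[::-1], t, right_t))
    vv = np.concatenate((left_v[::-1], v, right_v))
    if tt.size < 2:
        return np.full(n, vv[0] if vv.size else 0.0)
    if tt.size == 2:  # CubicSpline needs >= 2 points; 2 gives a line
        return np.interp(np.arange(n), tt, vv)
    return CubicSpline(tt, vv)(np.arange(n))


def _mean_envelope(
    h: np.ndarray, config: SiftConfig, first_pass: bool
) -> np.ndarray | None:
    maxima, minima = find_extrema(h)
    if maxima.size + minima.size < 3 or maxima.size == 0 or minima.size == 0:
        return None
    if config.halve_extrema and (first_pass or config.halve_each_pass):
        maxima, minima = halve_extrema(maxima, minima)
    upper = _envelope(maxima, h[maxima], h.size)
    lower = _envelope(minima, h[minima], h.size)
    return 0.5 * (upper + lower)


def _sift_stop_stat(m_prev: np.ndarray, m_cur: np.ndarray) -> float:
    denom = m_prev * m_prev
    ok = np.abs(m_prev) >= _DIV_GUARD
    if not np.any(ok):
        return 0.0
    diff = m_prev - m_cur
    return float(np.sum(diff[ok] ** 2 / denom[ok]))


def sift(signal: np.ndarray, config: SiftConfig | None = None) -> IMFSet:
    """Decompose a signal into IMFs + residue.

    Stops extracting IMFs when ``max_imfs`` is reached or the remaining
    signal has fewer than three extrema.
    """
    config = config or SiftConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise DataError("sift requires length >= 8")
    if not np.all(np.isfinite(x)):
        raise DataError("sift requires finite samples")

    imfs: list[np.ndarray] = []
    n_iters: list[int] = []
    residual = x.copy()
    max_sift_iter = max(1, min(x.size // 2, config.max_sift_iterations))
    for _ in range(config.max_imfs):
        h = residual.copy()
        m_prev = None
        iterations = 0
        for t in range(max_sift_iter):
            m = _mean_envelope(h, config, first_pass=(t == 0))
            if m is None:
                break
            h = h - m
            iterations += 1
            if m_prev is not None:
                if _sift_stop_stat(m_prev, m) < config.stop_threshold:
                    break
            m_prev = m
        if iterations == 0:
            break
        imfs.append(h)
        n_iters.append(iterations)
        residual = residual - h
        maxima, minima = find_extrema(residual)
        if maxima.size + minima.size < 3:
            break
    residue = x - (np.sum(imfs, axis=0) if imfs else 0.0)
    return IMFSet(
        source_length=x.size,
        imfs=imfs,
        residue=np.asarray(residue, dtype=float),
        n_sift_iterations=n_iters,
    )


def reconstruct(imfset: IMFSet) -> np.ndarray:
    """Element-wise sum of IMFs and residue."""
    total = imfset.residue.copy()
    for imf in imfset.imfs:
        total = total + imf
    return total
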