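"""Empirical mode decomposition and its noise-assisted ensemble variant.

``emd`` sifts a series into intrinsic mode functions (IMFs) using cubic
spline envelopes through the local extrema (extended by mirroring the two
outermost extrema past each end); sifting of one IMF stops when the
normalized squared change between successive siftings drops below 0.2 or
after 10 siftings, and decomposition stops when the residual has fewer
than two local extrema. The residual of ``eemd`` — the average over an
ensemble of decompositions of noise-perturbed copies — is the nonlinear
trend of the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["EEMDResult", "emd", "eemd", "count_extrema", "count_zero_crossings"]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateau runs contribute
    their midpoint."""
    d = np.diff(x)
    # collapse zero steps so plateaus register once
    idx_max, idx_min = [], []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                idx_max.append((i + j) // 2)
            i = j + 1
        elif x[i] < x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] > x[j]:
                idx_min.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx_max, dtype=int), np.asarray(idx_min, dtype=int)


def count_extrema(x: np.ndarray) -> int:
    mx, mn = _local_extrema(np.asarray(x, dtype=float))
    return len(mx) + len(mn)


def count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x[x != 0])
    return int(np.sum(s[1:] != s[:-1]))


def _envelope(t: np.ndarray, idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cubic spline through (t[idx], x[idx]) with the two outermost knots
    mirrored past each end to tame boundary swings."""
    ti, xi = t[idx].astype(float), x[idx]
    if len(ti) >= 2:
        left_t = 2 * t[0] - ti[1::-1]
        left_x = xi[1::-1]
        right_t = 2 * t[-1] - ti[:-3:-1]
        right_x = xi[:-3:-1]
        ti = np.concatenate([left_t, ti, right_t])
        xi = np.concatenate([left_x, xi, right_x])
    cs = CubicSpline(ti, xi)
    return cs(t)


def emd(series, sd_stop: float = 0.2, max_sift: int = 10,
        max_imfs: int | None = None) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose a series into IMFs and a residual; the reconstruction
    ``sum(imfs) + residual`` equals the input exactly."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for EMD (need >= 10 samples)")
    t = np.arange(n)
    if max_imfs is None:
        max_imfs = max(int(np.log2(n)), 1)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        mx, mn = _local_extrema(residual)
        if len(mx) + len(mn) < 2 or len(mx) < 2 or len(mn) < 2:
            break
        h = residual.copy()
        for _sift in range(max_sift):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            upper = _envelope(t, mx, h)
            lower = _envelope(t, mn, h)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h * h) + 1e-300
            sd = float(np.sum(mean_env * mean_env) / denom)
            h = h_new
            if sd < sd_stop:
                break
        imfs.append(h)
        residual = residual - h
        if count_extrema(residual) < 2:
            break
    return imfs, residual


@dataclass
class EEMDResult:
    imfs: list[np.ndarray]
    trend: np.ndarray                # averaged final residual
    ensemble_size: int
    noise_sd_fraction: float
    seed: int | None

    def reconstruction(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.trend if self.imfs else self.trend


def eemd(series, ensemble_size: int = 100, noise_sd_fraction: float = 0.2,
         seed: int | None = None) -> EEMDResult:
    """Ensemble EMD: average the decompositions of ``ensemble_size``
    white-noise-perturbed copies (noise SD = fraction × series SD), IMFs
    aligned by index and members short of the maximum padded with zeros."""
    x = np.asarray(series, dtype=float)
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = noise_sd_fraction * float(np.std(x))
    all_imfs: list[list[np.ndarray]] = []
    residuals = []
    for _ in range(ensemble_size):
        noisy = x + (rng.standard_normal(len(x)) * sigma if sigma > 0 else 0.0)
        imfs, res = emd(noisy)
        all_imfs.append(imfs)
        residuals.append(res)
    k = max((len(im) for im in all_imfs), default=0)
    mean_imfs = []
    for j in range(k):
        acc = np.zeros(len(x))
        for im in all_imfs:
            if j < len(im):
                acc += im[j]
        mean_imfs.append(acc / ensemble_size)
    trend = np.mean(residuals, axis=0)
    return EEMDResult(mean_imfs, trend, ensemble_size, noise_sd_fraction, seed)
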