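"""Fractal / complexity (FRD) feature extractors."""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateSignalError

_EPS = 1e-30


def _check(x, min_len, name):
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise DegenerateSignalError(
            f"{name}: needs >= {min_len} samples, got {x.size}"
        )
    return x


def higuchi_fd(x, fs=None, kmax=8):
    """Higuchi fractal dimension.

    Average normalized curve length L(k) over lags k = 1..kmax; the fractal
    dimension is the slope of log L(k) against log (1/k).  Smooth curves
    approach 1, white noise approaches 2.
    """
    x = _check(x, 3 * kmax + 2, f"HFD(kmax={kmax})")
    n = x.size
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (k * (idx.size - 1))
            lk.append(dist * norm / k)
        lengths[k - 1] = np.mean(lk)
    k_arr = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lengths + _EPS), 1)[0]
    return float(slope)


def fr4(x, fs=None):
    """Fourth-order fractal descriptor: Higuchi slope restricted to lags 1-4."""
    return higuchi_fd(x, kmax=4)


def dfa(x, fs=None, min_scale=4, n_scales=8):
    """Detrended fluctuation analysis scaling exponent alpha.

    The integrated profile is split into non-overlapping boxes per scale,
    linearly detrended per box, and the RMS fluctuation F(s) regressed as
    log F against log s.  White noise gives alpha near 0.5.
    """
    x = _check(x, 30, "DFA")
    profile = np.cumsum(x - np.mean(x))
    n = profile.size
    max_scale = n // 4
    scales = np.unique(
        np.geomspace(min_scale, max(max_scale, min_scale + 1), n_scales).astype(int)
    )
    flucts = []
    for s in scales:
        n_boxes = n // s
        segs = profile[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        # per-box linear detrend
        tm = t - t.mean()
        beta = segs @ tm / np.sum(tm ** 2)
        resid = segs - segs.mean(axis=1, keepdims=True) - np.outer(beta, tm)
        flucts.append(np.sqrt(np.mean(resid ** 2)))
    alpha = np.polyfit(np.log(scales), np.log(np.asarray(flucts) + _EPS), 1)[0]
    return float(alpha)


def approximate_entropy(x, fs=None, m=2, r_factor=0.2):
    """Approximate entropy ApEn(m, r) with r = r_factor * SD(x)."""
    x = _check(x, 10, "AEN")
    sd = np.std(x)
    if sd == 0:
        raise DegenerateSignalError("AEN: constant input")
    r = r_factor * sd
    n = x.size

    def phi(mm):
        count = n - mm + 1
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distances between all template pairs (self-match included)
        dists = np.max(
            np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1
        )
        c = np.count_nonzero(dists <= r, axis=1) / count
        return np.mean(np.log(c))

    return float(phi(m) - phi(m + 1))


def hjorth_activity(x, fs=None):
    x = _check(x, 3, "HJA")
    return float(np.var(x))


def hjorth_mobility(x, fs=None):
    x = _check(x, 3, "HJM")
    v = np.var(x)
    if v == 0:
        raise DegenerateSignalError("HJM: constant input")
    return float(np.sqrt(np.var(np.diff(x)) / v))


def hjorth_complexity(x, fs=None):
    x = _check(x, 4, "HJC")
    return float(hjorth_mobility(np.diff(x)) / hjorth_mobility(x))


def katz_fd(x, fs=None):
    """Katz fractal dimension ln(n) / (ln(n) + ln(d/L))."""
    x = _check(x, 3, "KFD")
    length = np.sum(np.abs(np.diff(x)))
    if length == 0:
        raise DegenerateSignalError("KFD: constant input")
    d = np.max(np.abs(x - x[0]))
    n = x.size - 1
    return float(np.log(n) / (np.log(n) + np.log(d / length + _EPS)))


def petrosian_fd(x, fs=None):
    """Petrosian fractal dimension from the sign-change count of the slope."""
    x = _check(x, 3, "PFD")
    d = np.diff(x)
    n_delta = np.count_nonzero(d[:-1] * d[1:] < 0)
    n = x.size
    return float(np.log(n) / (np.log(n) + np.log(n / (n + 0.4 * n_delta))))


def mfl(x, fs=None):
    """Maximum fractal length, ln sqrt(sum dx^2)."""
    x = _check(x, 2, "MFL")
    return float(np.log(np.sqrt(np.sum(np.diff(x) ** 2)) + _EPS))
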