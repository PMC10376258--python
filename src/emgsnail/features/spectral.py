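"""Frequency-domain (FD) feature extractors.

All descriptors are computed from the one-sided periodogram of the segment
(boxcar window, constant detrend).  Normalized descriptors (MNF, MDF, SEF95,
spectral entropy, ...) are invariant to amplitude scaling; power descriptors
(MNP, TTP, PSP, ...) scale quadratically.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..errors import DegenerateSignalError

_EPS = 1e-30

MIN_LEN = 16


def periodogram(x, fs):
    """One-sided periodogram; raises on an all-zero spectrum."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < MIN_LEN:
        raise DegenerateSignalError(
            f"spectral feature: segment of {x.size} samples < {MIN_LEN}"
        )
    f, p = sps.periodogram(x, fs=fs, detrend="constant")
    if not np.any(p > 0):
        raise DegenerateSignalError("spectral feature: all-zero spectrum")
    return f, p


def mnf(x, fs):
    """Power-weighted mean frequency."""
    f, p = periodogram(x, fs)
    return float(np.sum(f * p) / np.sum(p))


def mdf(x, fs):
    """Frequency splitting spectral power in half."""
    f, p = periodogram(x, fs)
    csum = np.cumsum(p)
    return float(f[np.searchsorted(csum, csum[-1] / 2.0)])


def mnp(x, fs):
    _, p = periodogram(x, fs)
    return float(np.mean(p))


def mnpd(x, fs, band=(20.0, 300.0)):
    """Mean power spectral density restricted to the EMG band."""
    f, p = periodogram(x, fs)
    lo, hi = band
    mask = (f >= lo) & (f <= min(hi, fs / 2))
    if not mask.any():
        mask = slice(None)
    return float(np.mean(p[mask]))


def ttp(x, fs):
    _, p = periodogram(x, fs)
    return float(np.sum(p))


def pkf(x, fs):
    f, p = periodogram(x, fs)
    return float(f[np.argmax(p)])


def psp(x, fs):
    """Power-spectrum peak value."""
    _, p = periodogram(x, fs)
    return float(np.max(p))


def psr(x, fs, half_width=20.0):
    """Power-spectrum ratio: power within +-half_width Hz of the peak / total."""
    f, p = periodogram(x, fs)
    f0 = f[np.argmax(p)]
    mask = np.abs(f - f0) <= half_width
    return float(np.sum(p[mask]) / np.sum(p))


def spectral_moment(x, fs, k=1):
    f, p = periodogram(x, fs)
    return float(np.sum(p * f ** k))


def sm1(x, fs):
    return spectral_moment(x, fs, 1)


def sm2(x, fs):
    return spectral_moment(x, fs, 2)


def sm3(x, fs):
    return spectral_moment(x, fs, 3)


def smn(x, fs):
    """Normalized spectral-moment shape ratio SM2 * TTP / SM1^2."""
    f, p = periodogram(x, fs)
    s1 = np.sum(p * f)
    s2 = np.sum(p * f ** 2)
    return float(s2 * np.sum(p) / (s1 ** 2 + _EPS))


def masp(x, fs):
    """Mean amplitude spectrum."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < MIN_LEN:
        raise DegenerateSignalError("MASP: segment too short")
    return float(np.mean(np.abs(np.fft.rfft(x))) / x.size)


def fdd(x, fs):
    """Frequency-distribution descriptor: spectral flatness (geometric over
    arithmetic mean of the periodogram, DC and empty bins excluded)."""
    _, p = periodogram(x, fs)
    q = p[1:]
    q = q[q > 0]
    if q.size == 0:
        raise DegenerateSignalError("FDD: empty spectrum")
    return float(np.exp(np.mean(np.log(q))) / np.mean(q))


def perc2(x, fs):
    """2nd-percentile frequency of the cumulative power distribution."""
    f, p = periodogram(x, fs)
    csum = np.cumsum(p)
    return float(f[np.searchsorted(csum, 0.02 * csum[-1])])


def vcf(x, fs):
    """Variance of the central frequency, SM2/TTP - MNF^2."""
    f, p = periodogram(x, fs)
    total = np.sum(p)
    mu = np.sum(f * p) / total
    return float(np.sum(p * f ** 2) / total - mu ** 2)


def sef95(x, fs):
    """95% spectral edge frequency."""
    f, p = periodogram(x, fs)
    csum = np.cumsum(p)
    return float(f[np.searchsorted(csum, 0.95 * csum[-1])])


def sent(x, fs):
    """Normalized spectral Shannon entropy in [0, 1]."""
    _, p = periodogram(x, fs)
    q = p / np.sum(p)
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)) / np.log(max(q.size, 2)))
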