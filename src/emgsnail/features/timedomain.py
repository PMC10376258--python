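"""Time-domain (TD) feature extractors.

All extractors take a single-channel sample vector ``x`` (and ignore the
sampling rate unless stated) and return a float or a fixed-length vector.
Amplitude thresholds default to a fraction of the segment RMS so that the
thresholded counts survive RMS normalization unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats

from ..errors import DegenerateSignalError

_EPS = 1e-12

#: Relative thresholds (fractions of segment RMS).
ZC_THRESHOLD = 0.01
SSC_THRESHOLD = 0.01
WAMP_THRESHOLD = 0.01
MYOP_THRESHOLD = 1.0
TURNS_THRESHOLD = 0.1
CARD_QUANTUM = 0.01


def _check(x: np.ndarray, min_len: int = 2, name: str = "feature") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise DegenerateSignalError(f"{name}: segment of {x.size} samples is too short")
    return x


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x ** 2)))


# -- amplitude and moment statistics ---------------------------------------

def mean(x, fs=None):
    return float(np.mean(_check(x)))


def mav(x, fs=None):
    return float(np.mean(np.abs(_check(x))))


def iemg(x, fs=None):
    return float(np.sum(np.abs(_check(x))))


def rms(x, fs=None):
    return _rms(_check(x))


def var(x, fs=None):
    x = _check(x)
    return float(np.sum(x ** 2) / (x.size - 1))


def ssi(x, fs=None):
    return float(np.sum(_check(x) ** 2))


def log_detector(x, fs=None):
    return float(np.exp(np.mean(np.log(np.abs(_check(x)) + _EPS))))


def msr(x, fs=None):
    return float(np.mean(np.sqrt(np.abs(_check(x)))))


def rsm0(x, fs=None):
    """Root-squared zero-order moment, sqrt(sum x^2)."""
    return float(np.sqrt(np.sum(_check(x) ** 2)))


def rsd1(x, fs=None):
    """Root-squared first-difference moment."""
    return float(np.sqrt(np.sum(np.diff(_check(x)) ** 2)))


def rsd2(x, fs=None):
    x = _check(x, 3)
    return float(np.sqrt(np.sum(np.diff(x, n=2) ** 2)))


def asm(x, fs=None):
    """Absolute second-difference (curvature) mean."""
    x = _check(x, 3)
    return float(np.mean(np.abs(np.diff(x, n=2))))


def rog(x, fs=None):
    """Ratio of gradient RMS to signal RMS (dimensionless)."""
    x = _check(x)
    return float(_rms(np.diff(x)) / (_rms(x) + _EPS))


def nsv(x, fs=None):
    """Accumulated negative slope value."""
    d = np.diff(_check(x))
    return float(np.sum(np.abs(d[d < 0])))


def er(x, fs=None):
    """Energy ratio of the first half of the window over the total."""
    x = _check(x)
    half = x.size // 2
    total = np.sum(x ** 2)
    return float(np.sum(x[:half] ** 2) / (total + _EPS))


def mavs(x, fs=None):
    """MAV slope: second-half MAV minus first-half MAV."""
    x = _check(x, 4)
    half = x.size // 2
    return float(np.mean(np.abs(x[half:])) - np.mean(np.abs(x[:half])))


def tm3(x, fs=None):
    return float(np.abs(np.mean(_check(x) ** 3)))


def tm4(x, fs=None):
    return float(np.mean(_check(x) ** 4))


def tm5(x, fs=None):
    return float(np.abs(np.mean(_check(x) ** 5)))


def v3(x, fs=None):
    return float(np.mean(np.abs(_check(x)) ** 3) ** (1.0 / 3.0))


def v4(x, fs=None):
    return float(np.mean(np.abs(_check(x)) ** 4) ** 0.25)


# -- waveform variation -----------------------------------------------------

def wl(x, fs=None):
    return float(np.sum(np.abs(np.diff(_check(x)))))


def aac(x, fs=None):
    x = _check(x)
    return float(np.sum(np.abs(np.diff(x))) / (x.size - 1))


def dasdv(x, fs=None):
    x = _check(x)
    return float(np.sqrt(np.sum(np.diff(x) ** 2) / (x.size - 1)))


def dvarv(x, fs=None):
    x = _check(x, 3)
    d = np.diff(x)
    return float(np.sum(d ** 2) / (d.size - 1))


def ewl(x, fs=None):
    """Enhanced waveform length: |dx|^0.75 in the central half, |dx|^0.5 outside."""
    x = _check(x, 3)
    d = np.abs(np.diff(x))
    n = d.size
    p = np.where((np.arange(n) >= n // 4) & (np.arange(n) < (3 * n) // 4), 0.75, 0.5)
    return float(np.sum(d ** p))


# -- thresholded counts -----------------------------------------------------

def zc(x, fs=None, threshold=None):
    """Zero crossings whose amplitude step exceeds the threshold."""
    x = _check(x)
    thr = ZC_THRESHOLD * _rms(x) if threshold is None else float(threshold)
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) > thr
    return float(np.count_nonzero(sign_change & big_enough))


def ssc(x, fs=None, threshold=None):
    """Slope-sign changes exceeding the threshold."""
    x = _check(x, 3)
    thr = SSC_THRESHOLD * _rms(x) ** 2 if threshold is None else float(threshold)
    v = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return float(np.count_nonzero(v > thr))


def wamp(x, fs=None, threshold=None):
    """Willison amplitude: steps larger than the threshold."""
    x = _check(x)
    thr = WAMP_THRESHOLD * _rms(x) if threshold is None else float(threshold)
    return float(np.count_nonzero(np.abs(np.diff(x)) > thr))


def myop(x, fs=None, threshold=None):
    """Myopulse percentage: fraction of samples above the threshold."""
    x = _check(x)
    thr = MYOP_THRESHOLD * _rms(x) if threshold is None else float(threshold)
    return float(np.mean(np.abs(x) > thr))


def turns(x, fs=None, threshold=None):
    """Willison-style turns: direction reversals with a large amplitude swing."""
    x = _check(x, 3)
    thr = TURNS_THRESHOLD * _rms(x) if threshold is None else float(threshold)
    d1, d2 = x[1:-1] - x[:-2], x[1:-1] - x[2:]
    return float(np.count_nonzero((d1 * d2 > 0) & (np.abs(d1) > thr) & (np.abs(d2) > thr)))


# -- weighted MAVs ----------------------------------------------------------

def mmav1(x, fs=None):
    x = np.abs(_check(x, 4))
    n = x.size
    i = np.arange(n)
    w = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    return float(np.mean(w * x))


def mmav2(x, fs=None):
    x = np.abs(_check(x, 4))
    n = x.size
    i = np.arange(n, dtype=float)
    w = np.ones(n)
    low = i < 0.25 * n
    high = i > 0.75 * n
    w[low] = 4.0 * i[low] / n
    w[high] = 4.0 * (n - i[high]) / n
    return float(np.mean(w * x))


def mmav5(x, fs=None):
    """Quintile-weighted MAV (weights 0.5/0.75/1/0.75/0.5 per fifth)."""
    x = np.abs(_check(x, 5))
    n = x.size
    quintile = np.minimum((np.arange(n) * 5) // n, 4)
    w = np.array([0.5, 0.75, 1.0, 0.75, 0.5])[quintile]
    return float(np.mean(w * x))


# -- amplitude cardinality --------------------------------------------------

def card(x, fs=None):
    """Count of distinct quantized amplitude levels."""
    x = _check(x)
    q = CARD_QUANTUM * (_rms(x) + _EPS)
    return float(np.unique(np.round(x / q)).size)


def crd(x, fs=None):
    """Cardinality by sorted-gap counting: 1 + #(sorted diffs > quantum)."""
    x = _check(x)
    q = CARD_QUANTUM * (_rms(x) + _EPS)
    return float(1 + np.count_nonzero(np.diff(np.sort(x)) > q))


# -- distribution statistics ------------------------------------------------

def std(x, fs=None):
    return float(np.std(_check(x), ddof=1))


def skw(x, fs=None):
    return float(stats.skew(_check(x, 3)))


def kurt(x, fs=None):
    return float(stats.kurtosis(_check(x, 4)))


def iqr(x, fs=None):
    return float(stats.iqr(_check(x)))


def mad(x, fs=None):
    x = _check(x)
    return float(np.median(np.abs(x - np.median(x))))


def amp_range(x, fs=None):
    x = _check(x)
    return float(np.max(x) - np.min(x))


def crest(x, fs=None):
    x = _check(x)
    return float(np.max(np.abs(x)) / (_rms(x) + _EPS))


def cov(x, fs=None):
    x = _check(x)
    return float(np.std(x, ddof=1) / (np.abs(np.mean(x)) + 1e-6 * _rms(x) + _EPS))


def meda(x, fs=None):
    return float(np.median(np.abs(_check(x))))


def maxa(x, fs=None):
    return float(np.max(np.abs(_check(x))))


def percentile_abs(x, fs=None, q=50.0):
    return float(np.percentile(np.abs(_check(x)), q))


# -- autoregressive and cepstral -------------------------------------------

def ar_coefficients(x, fs=None, order=4):
    """Burg-method AR coefficients (model x_t = sum a_i x_{t-i} + e_t)."""
    from statsmodels.regression.linear_model import burg

    x = _check(x, 2 * order + 1, name=f"AR{order}")
    if np.allclose(x, x[0]):
        raise DegenerateSignalError(f"AR{order}: constant input")
    coefs, _sigma2 = burg(x, order=order, demean=True)
    return np.asarray(coefs, dtype=float)


def cepstral_coefficients(x, fs=None, order=4):
    """Cepstral coefficients derived from Burg AR coefficients.

    Uses the standard recursion c_1 = -a_1,
    c_p = -a_p - sum_{l<p} (1 - l/p) a_l c_{p-l}, with a_i the negated AR
    parameters of the x_t = sum a_i x_{t-i} + e_t model.
    """
    a = -ar_coefficients(x, fs, order=order)
    c = np.zeros(order)
    c[0] = -a[0]
    for p in range(2, order + 1):
        acc = sum((1 - l / p) * a[l - 1] * c[p - l - 1] for l in range(1, p))
        c[p - 1] = -a[p - 1] - acc
    return c


# -- amplitude histogram ----------------------------------------------------

def hist_bin(x, fs=None, bin_index=0, n_bins=8):
    """Normalized occupancy of one amplitude-histogram bin over mean +- 3 SD."""
    x = _check(x)
    centre = np.mean(x)
    spread = np.std(x)
    if spread == 0:
        spread = 1.0
    counts, _ = np.histogram(x, bins=n_bins, range=(centre - 3 * spread, centre + 3 * spread))
    return float(counts[bin_index] / x.size)


# -- moment-shape descriptors ----------------------------------------------

def _m024(x):
    m0 = float(np.sum(x ** 2))
    m2 = float(np.sum(np.diff(x) ** 2))
    m4 = float(np.sum(np.diff(x, n=2) ** 2))
    return m0, m2, m4


def sparseness(x, fs=None):
    x = _check(x, 3)
    m0, m2, m4 = _m024(x)
    return float(np.log(m0 / (np.sqrt(np.abs((m0 - m2) * (m0 - m4))) + _EPS) + _EPS))


def irf(x, fs=None):
    """Irregularity factor m2 / sqrt(m0 * m4)."""
    x = _check(x, 3)
    m0, m2, m4 = _m024(x)
    return float(m2 / (np.sqrt(m0 * m4) + _EPS))


def wlr(x, fs=None):
    """Waveform-length ratio of first to second differences."""
    x = _check(x, 3)
    return float(np.sum(np.abs(np.diff(x))) / (np.sum(np.abs(np.diff(x, n=2))) + _EPS))


# -- Teager-Kaiser energy ---------------------------------------------------

def mtkeo(x, fs=None):
    x = _check(x, 3)
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(np.mean(psi))


def ltkeo(x, fs=None):
    v = mtkeo(x)
    return float(np.sign(v) * np.log1p(np.abs(v)))


# -- multiple-window energies ----------------------------------------------

def _window_energy(x, window):
    n = x.size
    length = max(4, (n + 1) // 2)
    starts = np.linspace(0, n - length, 3).astype(int)
    w = window(length)
    return float(sum(np.sum((x[s:s + length] * w) ** 2) for s in starts))


def mhw(x, fs=None):
    """Total energy over three half-length overlapping Hamming windows."""
    return _window_energy(_check(x, 8), sps.windows.hamming)


def _trapezoid(length):
    ramp = max(1, length // 5)
    w = np.ones(length)
    w[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    w[length - ramp:] = np.linspace(0.0, 1.0, ramp, endpoint=False)[::-1]
    return w


def mtw(x, fs=None):
    """Total energy over three half-length overlapping trapezoidal windows."""
    return _window_energy(_check(x, 8), _trapezoid)


# -- peak statistics --------------------------------------------------------

def mpk(x, fs=None):
    """Mean amplitude of |x| local maxima (max |x| if none)."""
    x = np.abs(_check(x, 3))
    peaks, _ = sps.find_peaks(x)
    return float(np.mean(x[peaks])) if peaks.size else float(np.max(x))


def npks(x, fs=None):
    """Local-maximum rate of |x| (peaks per sample)."""
    x = np.abs(_check(x, 3))
    peaks, _ = sps.find_peaks(x)
    return float(peaks.size / x.size)
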