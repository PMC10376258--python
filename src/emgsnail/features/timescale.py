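"""Time-frequency (TFD) feature extractors.

Short segments (the pipeline's analysis windows are 30-60 samples at
1000 Hz) are symmetrically padded to 64 samples before any decomposition.
Wavelet features use db4 with 3 levels; the empirical-wavelet features use a
fixed 10-band log-spaced partition of the spectrum so that EWT-4/6/8/10 and
EWP-4/6/8/10 index bands of one decomposition.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from ..errors import DegenerateSignalError

_EPS = 1e-30

WAVELET = "db4"
LEVELS = 3
N_EWT_BANDS = 10


def _prep(x, min_len=64, multiple=1, name="timescale feature"):
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise DegenerateSignalError(f"{name}: segment of {x.size} samples is too short")
    target = max(min_len, x.size)
    if target % multiple:
        target += multiple - target % multiple
    if target > x.size:
        x = np.pad(x, (0, target - x.size), mode="symmetric")
    return x


def dwt_band_energies(x, fs=None):
    """Raw band energies [approx, detail_L, ..., detail_1] of a 3-level DWT."""
    x = _prep(x, name="DWT")
    coeffs = pywt.wavedec(x, WAVELET, level=LEVELS, mode="symmetric")
    return np.array([float(np.sum(c ** 2)) for c in coeffs])


def dwt_log_energies(x, fs=None):
    return np.log(dwt_band_energies(x) + _EPS)


def swt_band_energies(x, fs=None):
    """Raw band energies [approx_L, detail_L, ..., detail_1] of a 3-level SWT."""
    x = _prep(x, multiple=2 ** LEVELS, name="SWT")
    coeffs = pywt.swt(x, WAVELET, level=LEVELS, norm=False)
    # coeffs[0] is the deepest level (cA_L, cD_L)
    energies = [float(np.sum(coeffs[0][0] ** 2))]
    energies += [float(np.sum(cd ** 2)) for _ca, cd in coeffs]
    return np.array(energies)


def swt_log_energies(x, fs=None):
    return np.log(swt_band_energies(x) + _EPS)


def stft_feature(x, fs):
    """Dispersion of short-time log-energy across frames."""
    x = _prep(x, name="STFT")
    nperseg = min(32, x.size)
    _f, _t, z = sps.stft(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    frame_energy = np.sum(np.abs(z) ** 2, axis=0)
    return float(np.std(np.log(frame_energy + _EPS)))


# -- empirical-wavelet band partition --------------------------------------

def ewt_band_edges(fs, n_bands=N_EWT_BANDS):
    """Fixed log-spaced band edges over (0, Nyquist]; first edge at Nyq/50."""
    nyq = fs / 2.0
    inner = np.geomspace(nyq / 50.0, nyq, n_bands)
    return np.concatenate([[0.0], inner])


def ewt_band_powers(x, fs, n_bands=N_EWT_BANDS):
    """(energies, relative powers) over the 10-band spectral partition."""
    x = _prep(x, name="EWT")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    spec = np.abs(np.fft.rfft(x)) ** 2
    edges = ewt_band_edges(fs, n_bands)
    energies = np.empty(n_bands)
    for k in range(n_bands):
        mask = (freqs > edges[k]) & (freqs <= edges[k + 1])
        if k == 0:
            mask |= freqs == 0.0
        energies[k] = np.sum(spec[mask])
    total = energies.sum()
    if total <= 0:
        raise DegenerateSignalError("EWT: zero-energy segment")
    return energies, energies / total


def ewt_energy(x, fs, band=1):
    """Log energy of one empirical-wavelet band (1-based index)."""
    energies, _ = ewt_band_powers(x, fs)
    return float(np.log(energies[band - 1] + _EPS))


def ewp_power(x, fs, band=1):
    """Relative power of one empirical-wavelet band (1-based index)."""
    _, powers = ewt_band_powers(x, fs)
    return float(powers[band - 1])


# -- Hilbert-Huang ----------------------------------------------------------

def _envelope_mean(h):
    """Mean of cubic-spline upper/lower envelopes; None if too few extrema."""
    from scipy.interpolate import CubicSpline

    n = h.size
    maxima, _ = sps.find_peaks(h)
    minima, _ = sps.find_peaks(-h)
    if maxima.size < 2 or minima.size < 2:
        return None
    t = np.arange(n)
    mx = np.concatenate([[0], maxima, [n - 1]])
    my = np.concatenate([[h[0]], h[maxima], [h[-1]]])
    upper = CubicSpline(mx, my)(t)
    mn = np.concatenate([[0], minima, [n - 1]])
    ny = np.concatenate([[h[0]], h[minima], [h[-1]]])
    lower = CubicSpline(mn, ny)(t)
    return 0.5 * (upper + lower)


def emd(x, max_imfs=3, max_siftings=12, sd_stop=0.2):
    """Empirical mode decomposition by standard cubic-spline sifting.

    Returns a list of IMFs (possibly empty for near-monotonic input); the
    residual is not returned.
    """
    r = np.asarray(x, dtype=float).ravel().copy()
    imfs = []
    for _ in range(max_imfs):
        h = r.copy()
        for _ in range(max_siftings):
            m = _envelope_mean(h)
            if m is None:
                break
            h_new = h - m
            denom = np.sum(h ** 2) + _EPS
            if np.sum((h_new - h) ** 2) / denom < sd_stop:
                h = h_new
                break
            h = h_new
        if _envelope_mean(h) is None and not imfs and np.allclose(h, r):
            break
        imfs.append(h)
        r = r - h
        maxima, _ = sps.find_peaks(r)
        minima, _ = sps.find_peaks(-r)
        if maxima.size + minima.size < 4:
            break
    return imfs


def hht_feature(x, fs):
    """Amplitude-weighted mean frequency of the Hilbert marginal spectrum
    over the empirical modes (falls back to the raw analytic signal when the
    segment has too few extrema to decompose)."""
    x = _prep(x, name="HHT")
    imfs = emd(x)
    if not imfs:
        imfs = [x - np.mean(x)]
    num = 0.0
    den = 0.0
    for imf in imfs:
        analytic = sps.hilbert(imf)
        amp = np.abs(analytic)[1:]
        phase = np.unwrap(np.angle(analytic))
        inst_f = np.clip(np.diff(phase) * fs / (2 * np.pi), 0.0, fs / 2.0)
        num += float(np.sum(amp ** 2 * inst_f))
        den += float(np.sum(amp ** 2))
    return num / (den + _EPS)
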