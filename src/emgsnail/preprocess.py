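"""Filtering, normalization and peak-locked gesture-window autodetection.

The fixed pipeline order is bandpass -> hampel -> rms_normalize ->
detect_gestures (asserted by :func:`preprocess_pipeline`).  Band-pass
filtering is zero-phase (forward-backward) so that burst peak timing is
preserved for the short 30-60 ms analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter

from .errors import ConfigurationError, DegenerateSignalError
from .signals import Recording, Segment

#: Consistent robust-scale factor: for Gaussian data, MAD * 1.4826 estimates
#: one standard deviation.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + Hampel + RMS-normalization parameters."""

    band: tuple[float, float] = (20.0, 300.0)
    order: int = 4
    hampel_window: int = 100
    hampel_nsigma: float = 2.0
    target_rms: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ConfigurationError(f"invalid band {self.band}")
        if self.order < 2 or self.order % 2:
            raise ConfigurationError("order must be an even integer >= 2")
        if self.hampel_window < 3:
            raise ConfigurationError("hampel_window must be >= 3")
        if self.target_rms <= 0:
            raise ConfigurationError("target_rms must be > 0")


@dataclass(frozen=True)
class DetectionSpec:
    """Peak-locked window detection parameters.

    Windows span ``sup_fraction`` of their length before the envelope peak
    and ``inf_fraction`` after it, with the length clamped to
    [min_window_ms, max_window_ms].
    """

    min_window_ms: float = 30.0
    max_window_ms: float = 60.0
    sup_fraction: float = 1.0 / 3.0
    inf_fraction: float = 2.0 / 3.0
    envelope_window_ms: float = 100.0
    min_separation_ms: float = 200.0
    threshold_nsigma: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.min_window_ms <= self.max_window_ms):
            raise ConfigurationError("need 0 < min_window_ms <= max_window_ms")
        for frac in (self.sup_fraction, self.inf_fraction):
            if not 0 < frac < 1:
                raise ConfigurationError("fractions must be in (0, 1)")
        if self.envelope_window_ms <= 0:
            raise ConfigurationError("envelope_window_ms must be > 0")


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    lo, hi = spec.band
    if hi >= rec.fs / 2:
        raise ConfigurationError(
            f"band upper edge {hi} Hz >= Nyquist {rec.fs / 2} Hz"
        )
    sos = sps.butter(spec.order, (lo, hi), btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.with_samples(filtered)


def hampel(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Sliding-window outlier rejection.

    A sample deviating from its window median by more than
    ``nsigma * 1.4826 * MAD`` is replaced by that median; all other samples
    pass through unchanged.  The first and last half-windows, where no full
    centred window exists, are left untouched.
    """
    size = spec.hampel_window | 1  # centred window needs an odd size
    x = rec.samples
    med = median_filter(x, size=(size, 1), mode="nearest")
    mad = median_filter(np.abs(x - med), size=(size, 1), mode="nearest")
    thresh = spec.hampel_nsigma * MAD_SCALE * mad
    out = np.where(np.abs(x - med) > thresh, med, x)
    half = size // 2
    out[:half] = x[:half]
    out[x.shape[0] - half:] = x[x.shape[0] - half:]
    return rec.with_samples(out)


def rms_normalize(rec: Recording, target_rms: float = 1.0) -> Recording:
    """Scale each channel so its RMS equals ``target_rms``."""
    rms = np.sqrt(np.mean(rec.samples ** 2, axis=0))
    zero = np.flatnonzero(rms == 0)
    if zero.size:
        raise DegenerateSignalError(
            f"channel(s) {zero.tolist()} are all-zero; cannot RMS-normalize"
        )
    return rec.with_samples(rec.samples * (target_rms / rms))


def rms_envelope(rec: Recording, window_ms: float = 100.0) -> np.ndarray:
    """Per-sample moving-RMS envelope summed over channels."""
    n = max(3, int(round(window_ms * rec.fs / 1000.0)))
    kernel = np.ones(n) / n
    power = rec.samples ** 2
    smoothed = np.apply_along_axis(
        lambda c: np.convolve(c, kernel, mode="same"), 0, power
    )
    return np.sqrt(smoothed).sum(axis=1)


def detect_gestures(
    rec: Recording, spec: DetectionSpec = DetectionSpec()
) -> list[Segment]:
    """Detect gesture bursts and emit peak-locked unlabeled windows.

    Peaks of the summed RMS envelope above an adaptive threshold
    (median + nsigma * 1.4826 * MAD of the envelope) become window anchors;
    each window covers ``sup_fraction`` of its span before the peak and
    ``inf_fraction`` after, clamped to the configured duration bounds.
    Overlap conflicts are resolved in favour of the higher peak.  Returned
    segments carry the placeholder label ``"rest"`` until classified.
    """
    env_n = int(round(spec.envelope_window_ms * rec.fs / 1000.0))
    if rec.n_samples < env_n:
        raise DegenerateSignalError(
            f"recording of {rec.n_samples} samples shorter than one envelope window"
        )
    env = rms_envelope(rec, spec.envelope_window_ms)
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    # robust adaptive threshold with a relative floor so a homogeneous
    # (burst-free) envelope yields no detections
    threshold = med + max(spec.threshold_nsigma * MAD_SCALE * mad, 0.2 * med)

    distance = max(1, int(round(spec.min_separation_ms * rec.fs / 1000.0)))
    peaks, props = sps.find_peaks(env, height=threshold, distance=distance)
    if peaks.size == 0:
        return []

    win = int(round(spec.max_window_ms * rec.fs / 1000.0))
    win_min = int(round(spec.min_window_ms * rec.fs / 1000.0))
    win = max(win, win_min)

    order = np.argsort(props["peak_heights"])[::-1]  # higher peak wins ties
    taken: list[tuple[int, int]] = []
    windows: list[tuple[int, int]] = []
    for idx in order:
        peak = int(peaks[idx])
        start = peak - int(round(spec.sup_fraction * win))
        start = int(np.clip(start, 0, rec.n_samples - win))
        end = start + win
        if any(start < t1 and t0 < end for t0, t1 in taken):
            continue
        taken.append((start, end))
        windows.append((start, end))

    windows.sort()
    return [
        Segment(
            window=rec.samples[s:e],
            label="rest",
            subject_id=rec.subject_id,
            onset_index=s,
            channel_roles=rec.channel_roles,
            fs=rec.fs,
        )
        for s, e in windows
    ]


def preprocess_pipeline(
    rec: Recording,
    filter_spec: FilterSpec = FilterSpec(),
    detection_spec: DetectionSpec | None = None,
):
    """Fixed-order pipeline: bandpass -> hampel -> rms_normalize [-> detect].

    Returns the cleaned Recording, or ``(recording, segments)`` when a
    DetectionSpec is given.
    """
    cleaned = rms_normalize(
        hampel(bandpass(rec, filter_spec), filter_spec), filter_spec.target_rms
    )
    if detection_spec is None:
        return cleaned
    return cleaned, detect_gestures(cleaned, detection_spec)
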