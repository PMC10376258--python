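"""Core signal/label data types and a synthetic hemiplegic-EMG generator.

The generator is a statistical stand-in for a clinical acquisition that is not
publicly available: 19 post-stroke subjects, five bipolar surface-EMG channels
(two forearm-flexor, two forearm-extensor, one thenar) sampled at 1000 Hz,
six hand gestures repeated ten times each plus a rest class.  Muscle activity
is modelled as band-limited (20-300 Hz) zero-mean Gaussian noise, amplitude
modulated by a smooth burst envelope whose per-channel amplitude profile is
gesture specific.  Per-subject gain variability, inter-channel crosstalk, a
severity factor that shrinks gesture profiles toward the rest profile, and
optional spike artifacts emulate the main nuisance structure of paretic
recordings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DegenerateSignalError, FormatError

#: The seven gesture classes (six volitional gestures + rest).
GESTURES = (
    "fist",
    "pinch",
    "wrist_flexion",
    "wrist_extension",
    "palm_open",
    "thumb",
)
REST = "rest"
LABELS = GESTURES + (REST,)

CHANNEL_ROLES_DEFAULT = ("flexor", "flexor", "extensor", "extensor", "thenar")

# Gesture -> per-role-channel envelope amplitude profile (arbitrary units).
# Rows are distinct directions in channel space so that envelope-amplitude
# features separate the classes when severity is 1.
_PROFILES = {
    "fist": (1.00, 0.90, 0.30, 0.25, 0.70),
    "pinch": (0.40, 0.30, 0.25, 0.20, 1.00),
    "wrist_flexion": (1.00, 0.80, 0.15, 0.20, 0.20),
    "wrist_extension": (0.20, 0.15, 1.00, 0.80, 0.20),
    "palm_open": (0.30, 0.35, 0.90, 0.70, 0.60),
    "thumb": (0.55, 0.20, 0.20, 0.45, 0.95),
}
_REST_LEVEL = 0.05


@dataclass(frozen=True)
class Recording:
    """A multi-channel surface-EMG recording.

    samples : (time, channels) float array, arbitrary amplitude units
    fs : sampling rate in Hz
    subject_id : participant identifier
    channel_roles : per-channel anatomical tag (flexor | extensor | thenar)
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    channel_roles: tuple[str, ...] = CHANNEL_ROLES_DEFAULT

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] < 1:
            raise ConfigurationError("samples must be a (time, channels) matrix")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples contain non-finite values")
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if len(self.channel_roles) != samples.shape[1]:
            raise ConfigurationError(
                f"{len(self.channel_roles)} roles for {samples.shape[1]} channels"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class Segment:
    """A windowed excerpt of a Recording with its gesture-class label."""

    window: np.ndarray
    label: str
    subject_id: str
    onset_index: int
    channel_roles: tuple[str, ...] = CHANNEL_ROLES_DEFAULT
    fs: float = 1000.0

    def __post_init__(self) -> None:
        window = np.asarray(self.window, dtype=float)
        if window.ndim != 2 or window.shape[0] < 2:
            raise ConfigurationError("segment window needs >= 2 samples")
        if self.label not in LABELS:
            raise ConfigurationError(f"unknown label {self.label!r}")
        if self.onset_index < 0:
            raise ConfigurationError("onset_index must be >= 0")
        object.__setattr__(self, "window", window)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for the synthetic hemiplegic-EMG dataset.

    severity scales class separability per subject: 1 keeps the full gesture
    profile, 0 collapses every gesture onto the rest profile.  A scalar is
    broadcast to all subjects.
    """

    n_subjects: int = 19
    n_channels: int = 5
    fs: float = 1000.0
    reps_per_gesture: int = 10
    burst_band: tuple[float, float] = (20.0, 300.0)
    subject_gain_sd: float = 0.2
    crosstalk: float = 0.05
    severity: float | Sequence[float] = 1.0
    artifact_rate: float = 0.0
    seed: int = 0
    burst_ms: tuple[float, float] = (200.0, 400.0)
    gap_ms: tuple[float, float] = (250.0, 600.0)
    amplitude: float = 100.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1 or self.reps_per_gesture < 1:
            raise ConfigurationError("counts must be positive")
        if not self.fs > 0:
            raise ConfigurationError("fs must be > 0")
        lo, hi = self.burst_band
        if not (0 < lo < hi < self.fs / 2):
            raise ConfigurationError(
                f"burst_band {self.burst_band} must lie inside (0, fs/2)"
            )
        if self.subject_gain_sd < 0 or self.artifact_rate < 0:
            raise ConfigurationError("subject_gain_sd and artifact_rate must be >= 0")
        if not 0 <= self.crosstalk < 1:
            raise ConfigurationError("crosstalk must be in [0, 1)")
        sev = np.atleast_1d(np.asarray(self.severity, dtype=float))
        if not np.all(np.isfinite(sev)) or np.any(sev < 0) or np.any(sev > 1):
            raise ConfigurationError("severity values must be finite in [0, 1]")
        if sev.size not in (1, self.n_subjects):
            raise ConfigurationError("severity must be scalar or one value per subject")

    def severity_per_subject(self) -> np.ndarray:
        sev = np.atleast_1d(np.asarray(self.severity, dtype=float))
        if sev.size == 1:
            sev = np.full(self.n_subjects, sev[0])
        return sev


@dataclass
class SynthDataset:
    """Recordings plus burst-level ground truth annotations."""

    recordings: list[Recording]
    annotations: list[dict]
    config: SynthConfig = field(repr=False, default=None)

    def annotations_for(self, subject_id: str) -> list[dict]:
        return [a for a in self.annotations if a["subject_id"] == subject_id]


def _roles_for(n_channels: int) -> tuple[str, ...]:
    if n_channels == len(CHANNEL_ROLES_DEFAULT):
        return CHANNEL_ROLES_DEFAULT
    # Alternate flexor/extensor, last channel thenar.
    roles = ["flexor" if i % 2 == 0 else "extensor" for i in range(n_channels)]
    roles[-1] = "thenar"
    return tuple(roles)


def _profile_matrix(n_channels: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(123456789)  # fixed design, not a run seed
    out: dict[str, np.ndarray] = {}
    for gesture, base in _PROFILES.items():
        prof = np.asarray(base, dtype=float)
        if n_channels <= prof.size:
            out[gesture] = prof[:n_channels].copy()
        else:
            extra = rng.uniform(0.2, 1.0, n_channels - prof.size)
            out[gesture] = np.concatenate([prof, extra])
    return out


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to `band`, unit RMS."""
    pad = max(int(0.1 * fs), 32)
    x = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)[pad:pad + n]
    rms = np.sqrt(np.mean(y ** 2))
    return y / max(rms, 1e-12)


def _burst_envelope(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth unit-peak envelope: Tukey ramp times a slow random modulation."""
    env = sps.windows.tukey(n, alpha=0.5)
    t = np.linspace(0, 1, n)
    f = rng.uniform(1.5, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    mod = 1.0 + 0.25 * np.sin(2 * np.pi * f * t + phase)
    env = env * mod
    return env / env.max()


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate one recording per subject plus burst-level ground truth.

    Deterministic given ``cfg.seed``.  Each subject's recording contains
    ``reps_per_gesture`` bursts per gesture class, in randomized order,
    separated by rest spans of baseline activity.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles = _profile_matrix(cfg.n_channels)
    roles = _roles_for(cfg.n_channels)
    severities = cfg.severity_per_subject()
    rest_profile = np.full(cfg.n_channels, _REST_LEVEL)

    recordings: list[Recording] = []
    annotations: list[dict] = []
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:02d}"
        gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd)))
        sev = severities[s]

        schedule = [g for g in GESTURES for _ in range(cfg.reps_per_gesture)]
        rng.shuffle(schedule)

        chunks: list[np.ndarray] = []
        cursor = 0

        def rest_span(dur_ms: float) -> np.ndarray:
            n = int(round(dur_ms * cfg.fs / 1000.0))
            noise = np.column_stack(
                [_band_noise(rng, n, cfg.burst_band, cfg.fs) for _ in range(cfg.n_channels)]
            )
            return noise * rest_profile * cfg.amplitude * gain

        lead = rest_span(rng.uniform(*cfg.gap_ms))
        chunks.append(lead)
        cursor += lead.shape[0]

        for gesture in schedule:
            dur_ms = rng.uniform(*cfg.burst_ms)
            n = int(round(dur_ms * cfg.fs / 1000.0))
            profile = rest_profile + sev * (profiles[gesture] - rest_profile)
            env = _burst_envelope(rng, n)
            burst = np.column_stack(
                [_band_noise(rng, n, cfg.burst_band, cfg.fs) for _ in range(cfg.n_channels)]
            )
            burst = burst * env[:, None] * profile * cfg.amplitude * gain
            annotations.append(
                {
                    "subject_id": subject_id,
                    "onset": cursor,
                    "duration": n,
                    "label": gesture,
                }
            )
            chunks.append(burst)
            cursor += n
            gap = rest_span(rng.uniform(*cfg.gap_ms))
            chunks.append(gap)
            cursor += gap.shape[0]

        samples = np.concatenate(chunks, axis=0)

        if cfg.crosstalk > 0 and cfg.n_channels > 1:
            mix = np.full(
                (cfg.n_channels, cfg.n_channels),
                cfg.crosstalk / (cfg.n_channels - 1),
            )
            np.fill_diagonal(mix, 1.0 - cfg.crosstalk)
            samples = samples @ mix.T

        if cfg.artifact_rate > 0:
            duration_s = samples.shape[0] / cfg.fs
            for ch in range(cfg.n_channels):
                n_spikes = rng.poisson(cfg.artifact_rate * duration_s)
                for _ in range(n_spikes):
                    idx = int(rng.integers(50, samples.shape[0] - 50))
                    local = samples[idx - 50:idx + 50, ch]
                    local_rms = max(np.sqrt(np.mean(local ** 2)), 1e-9)
                    samples[idx, ch] += rng.choice([-1.0, 1.0]) * 12.0 * local_rms

        recordings.append(
            Recording(samples=samples, fs=cfg.fs, subject_id=subject_id,
                      channel_roles=roles)
        )

    return SynthDataset(recordings=recordings, annotations=annotations, config=cfg)


def segments_from_annotations(
    dataset: SynthDataset,
    window_ms: float = 60.0,
    rest_per_subject: int | None = None,
) -> list[Segment]:
    """Cut peak-centred labelled windows from ground-truth bursts.

    Each gesture burst yields one window of ``window_ms`` centred on the burst
    midpoint; in addition ``rest_per_subject`` windows (default: one per
    gesture repetition) are sampled deterministically from inter-burst spans.
    """
    cfg = dataset.config
    win = int(round(window_ms * cfg.fs / 1000.0))
    if rest_per_subject is None:
        rest_per_subject = cfg.reps_per_gesture
    segments: list[Segment] = []
    rng = np.random.default_rng((cfg.seed, 0xE5E))
    for rec in dataset.recordings:
        anns = sorted(dataset.annotations_for(rec.subject_id), key=lambda a: a["onset"])
        for ann in anns:
            centre = ann["onset"] + ann["duration"] // 2
            start = max(0, min(centre - win // 2, rec.n_samples - win))
            segments.append(
                Segment(
                    window=rec.samples[start:start + win],
                    label=ann["label"],
                    subject_id=rec.subject_id,
                    onset_index=start,
                    channel_roles=rec.channel_roles,
                    fs=rec.fs,
                )
            )
        # rest windows from gaps between consecutive bursts
        gaps = []
        prev_end = 0
        for ann in anns:
            if ann["onset"] - prev_end >= 2 * win:
                gaps.append((prev_end, ann["onset"]))
            prev_end = ann["onset"] + ann["duration"]
        if rec.n_samples - prev_end >= 2 * win:
            gaps.append((prev_end, rec.n_samples))
        for _ in range(rest_per_subject):
            if not gaps:
                break
            g0, g1 = gaps[int(rng.integers(len(gaps)))]
            margin = win // 2
            start = int(rng.integers(g0 + margin, g1 - win - margin + 1))
            segments.append(
                Segment(
                    window=rec.samples[start:start + win],
                    label=REST,
                    subject_id=rec.subject_id,
                    onset_index=start,
                    channel_roles=rec.channel_roles,
                    fs=rec.fs,
                )
            )
    return segments


def planted_feature_matrix(
    n_subjects: int = 12,
    reps_per_class: int = 3,
    n_informative: int = 5,
    n_noise: int = 20,
    separation: float = 2.0,
    severity: float = 1.0,
    subject_sd: float = 0.3,
    seed: int = 0,
):
    """A feature matrix with known informative columns, for search recovery.

    Informative feature j carries class-specific means (drawn once from a
    fixed design RNG, scaled by ``separation * severity``) plus a per-subject
    offset and unit noise; noise features are pure N(0, 1).  Returns an
    :class:`emgsnail.features.FeatureMatrix` whose informative features are
    named ``INF1..`` and noise features ``NSE1..``.
    """
    from .features import FeatureMatrix  # local import avoids a cycle

    design = np.random.default_rng(987654321)
    centres = design.normal(0.0, 1.0, size=(len(LABELS), n_informative))

    rng = np.random.default_rng(seed)
    labels, subjects, rows = [], [], []
    for s in range(n_subjects):
        offset = rng.normal(0.0, subject_sd, size=n_informative + n_noise)
        for ci, label in enumerate(LABELS):
            for _ in range(reps_per_class):
                inf = separation * severity * centres[ci] + rng.standard_normal(n_informative)
                nse = rng.standard_normal(n_noise)
                rows.append(np.concatenate([inf, nse]) + offset)
                labels.append(label)
                subjects.append(f"S{s + 1:02d}")
    names = [f"INF{i + 1}" for i in range(n_informative)] + [
        f"NSE{i + 1}" for i in range(n_noise)
    ]
    columns = [(name, 0) for name in names]
    return FeatureMatrix(
        values=np.asarray(rows),
        columns=columns,
        labels=np.asarray(labels),
        subjects=np.asarray(subjects),
    )


# ---------------------------------------------------------------------------
# I/O: delimited interchange format (primary) and EDF (optional)
# ---------------------------------------------------------------------------

def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a Recording as CSV (header = channel roles) + JSON sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(rec.channel_roles)
        for row in rec.samples:
            writer.writerow([repr(float(v)) for v in row])
    sidecar = {"fs": rec.fs, "subject_id": rec.subject_id}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_recording(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a Recording from a delimited file or an EDF file.

    Delimited dialect: one header row of channel roles, one column per
    channel; the sampling rate comes from the JSON sidecar written by
    :func:`write_recording`, or from the ``fs`` argument.  EDF reading uses
    ``mne`` and takes fs from the embedded header.
    """
    path = Path(path)
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FormatError("EDF support requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        samples = raw.get_data().T
        roles = tuple(raw.ch_names)
        return Recording(samples=samples, fs=float(raw.info["sfreq"]),
                         subject_id=subject_id or path.stem, channel_roles=roles)
    if format != "delimited":
        raise FormatError(f"unknown format {format!r}")

    sidecar_path = path.with_suffix(path.suffix + ".json")
    if fs is None:
        if not sidecar_path.exists():
            raise FormatError(f"missing fs: no sidecar {sidecar_path.name} and no fs argument")
        meta = json.loads(sidecar_path.read_text())
        fs = float(meta["fs"])
        subject_id = subject_id or meta.get("subject_id")

    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            roles = tuple(next(reader))
        except StopIteration:
            raise FormatError(f"{path.name}: empty file") from None
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(roles):
                raise FormatError(
                    f"{path.name}: line {lineno} has {len(row)} fields, expected {len(roles)}"
                )
            try:
                rows.append([float(v) for v in row])
            except ValueError:
                bad = next(v for v in row if not _is_float(v))
                raise FormatError(
                    f"{path.name}: line {lineno}: non-numeric cell {bad!r}"
                ) from None
    if not rows:
        raise FormatError(f"{path.name}: no data rows")
    return Recording(samples=np.asarray(rows), fs=fs,
                     subject_id=subject_id or path.stem, channel_roles=roles)


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False
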