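"""Multi-domain EMG feature bank: registry, extraction, feature matrices.

The default registry holds 127 named features across five domains — time
(TD), frequency (FD), time-frequency (TFD), fractal (FRD) and spatial (SD)
— mirroring the breadth of hand-crafted descriptors used in myoelectric
pattern recognition, including logarithmic variants of selected features.
Channel features are extracted per channel and concatenated; spatial
features compare muscle groups across channels and are computed once per
segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import partial
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np

from ..errors import DegenerateSignalError, RegistryError
from ..signals import Segment
from . import fractal, spatial, spectral, timedomain as td, timescale

DOMAINS = ("TD", "FD", "TFD", "FRD", "SD")


@dataclass(frozen=True)
class FeatureSpec:
    """Registry entry: a named extractor with its domain and output arity."""

    name: str
    domain: str
    func: Callable
    arity: int = 1
    kind: str = "channel"  # "channel" (per-channel) or "spatial" (cross-channel)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise RegistryError(f"{self.name}: unknown domain {self.domain}")
        if self.arity < 1:
            raise RegistryError(f"{self.name}: arity must be >= 1")


def log_variant(spec: FeatureSpec, name: str | None = None,
                eps_scale: float = 1.0) -> FeatureSpec:
    """Logarithmic variant of a registered feature.

    Computes sign(v) * ln(1 + |v| / eps_scale) of the base feature value,
    preserving sign and monotonicity.
    """
    base = spec.func

    def _logged(*args, **kwargs):
        v = np.asarray(base(*args, **kwargs), dtype=float)
        out = np.sign(v) * np.log1p(np.abs(v) / eps_scale)
        return float(out) if out.ndim == 0 else out

    return replace(spec, name=name or ("L" + spec.name), func=_logged)


class FeatureRegistry:
    """Ordered collection of FeatureSpec with alias-tolerant lookup."""

    def __init__(self, specs: Sequence[FeatureSpec]):
        self._specs: list[FeatureSpec] = []
        self._by_name: dict[str, FeatureSpec] = {}
        self._aliases: dict[str, str] = {}
        for spec in specs:
            self.register(spec)

    @staticmethod
    def _normalize(name: str) -> str:
        return "".join(c for c in name.upper() if c.isalnum())

    def register(self, spec: FeatureSpec) -> None:
        if spec.name in self._by_name:
            raise RegistryError(f"duplicate feature name {spec.name!r}")
        key = self._normalize(spec.name)
        if key in self._aliases:
            raise RegistryError(
                f"{spec.name!r} collides with {self._aliases[key]!r} after normalization"
            )
        self._specs.append(spec)
        self._by_name[spec.name] = spec
        self._aliases[key] = spec.name

    def resolve(self, name: str) -> FeatureSpec:
        """Look up a feature, tolerating punctuation variants (AR-4 == AR4)."""
        if name in self._by_name:
            return self._by_name[name]
        key = self._normalize(name)
        if key in self._aliases:
            return self._by_name[self._aliases[key]]
        raise RegistryError(f"unknown feature {name!r}")

    @property
    def specs(self) -> tuple[FeatureSpec, ...]:
        return tuple(self._specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self._specs)

    def domain_of(self, name: str) -> str:
        return self.resolve(name).domain

    def subset(self, names: Iterable[str]) -> "FeatureRegistry":
        keep = {self.resolve(n).name for n in names}
        return FeatureRegistry([s for s in self._specs if s.name in keep])

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except RegistryError:
            return False

    def manifest(self) -> list[dict]:
        return [
            {"name": s.name, "domain": s.domain, "arity": s.arity,
             "kind": s.kind, "params": s.params}
            for s in self._specs
        ]


def _chan(name, domain, func, arity=1, **params):
    f = partial(func, **params) if params else func
    return FeatureSpec(name=name, domain=domain, func=f, arity=arity,
                       params=params)


def _spatial(name, func, **params):
    f = partial(func, **params) if params else func
    return FeatureSpec(name=name, domain="SD", func=f, kind="spatial",
                       params=params)


def _build_specs() -> list[FeatureSpec]:
    specs: list[FeatureSpec] = []
    C = _chan

    # ------------------------------------------------------------------ TD
    base_for_logs = {}
    for name, func in [
        ("MEAN", td.mean), ("MAV", td.mav), ("IEMG", td.iemg), ("RMS", td.rms),
        ("VAR", td.var), ("SSI", td.ssi), ("LOG", td.log_detector),
        ("MSR", td.msr), ("RSM0", td.rsm0), ("RSD1", td.rsd1), ("RSD2", td.rsd2),
        ("ASM", td.asm), ("ROG", td.rog), ("NSV", td.nsv), ("ER", td.er),
        ("MAVS", td.mavs), ("TM3", td.tm3), ("TM4", td.tm4), ("TM5", td.tm5),
        ("V3", td.v3), ("V4", td.v4),
        ("WL", td.wl), ("AAC", td.aac), ("DASDV", td.dasdv), ("EWL", td.ewl),
        ("DVARV", td.dvarv),
        ("ZC", td.zc), ("SSC", td.ssc), ("WAMP", td.wamp), ("MYOP", td.myop),
        ("MMAV1", td.mmav1), ("MMAV2", td.mmav2), ("MMAV5", td.mmav5),
        ("CARD", td.card), ("CRD", td.crd),
        ("STD", td.std), ("SKW", td.skw), ("KURT", td.kurt), ("IQR", td.iqr),
        ("MAD", td.mad), ("RANGE", td.amp_range), ("CREST", td.crest),
        ("COV", td.cov), ("MEDA", td.meda), ("MAXA", td.maxa),
        ("SPARSE", td.sparseness), ("IRF", td.irf), ("WLR", td.wlr),
        ("MTKEO", td.mtkeo), ("LTKEO", td.ltkeo),
        ("MHW", td.mhw), ("MTW", td.mtw),
        ("MPK", td.mpk), ("NPKS", td.npks), ("TURNS", td.turns),
    ]:
        spec = C(name, "TD", func)
        specs.append(spec)
        base_for_logs[name] = spec

    for q, name in [(10, "P10"), (25, "P25"), (75, "P75"), (90, "P90")]:
        specs.append(C(name, "TD", td.percentile_abs, q=q))

    for order in range(2, 7):
        specs.append(C(f"AR{order}", "TD", td.ar_coefficients,
                       arity=order, order=order))
    specs.append(C("CC-R", "TD", td.cepstral_coefficients, arity=4, order=4))

    for b in range(8):
        specs.append(C(f"HIST{b + 1}", "TD", td.hist_bin, bin_index=b))

    # logarithmic interpretations of selected TD features
    for base in ("MAV", "SSI", "VAR", "WL", "RMS", "IEMG", "CARD"):
        specs.append(log_variant(base_for_logs[base]))

    # ------------------------------------------------------------------ FD
    for name, func in [
        ("MNF", spectral.mnf), ("MDF", spectral.mdf), ("MNP", spectral.mnp),
        ("MNPD", spectral.mnpd), ("TTP", spectral.ttp), ("PKF", spectral.pkf),
        ("PSR", spectral.psr), ("PSP", spectral.psp),
        ("SM1", spectral.sm1), ("SM2", spectral.sm2), ("SM3", spectral.sm3),
        ("SMN", spectral.smn), ("MASP", spectral.masp), ("FDD", spectral.fdd),
        ("PERC2", spectral.perc2), ("VCF", spectral.vcf),
        ("SEF95", spectral.sef95), ("SENT", spectral.sent),
    ]:
        specs.append(C(name, "FD", func))
    masp_spec = next(s for s in specs if s.name == "MASP")
    specs.append(log_variant(masp_spec, name="MLASP"))

    # ----------------------------------------------------------------- TFD
    specs.append(C("DWT", "TFD", timescale.dwt_log_energies, arity=4))
    specs.append(C("SWT", "TFD", timescale.swt_log_energies, arity=4))
    specs.append(C("STFT", "TFD", timescale.stft_feature))
    specs.append(C("HHT", "TFD", timescale.hht_feature))
    for k in (4, 6, 8, 10):
        specs.append(C(f"EWT-{k}", "TFD", timescale.ewt_energy, band=k))
    for k in (4, 6, 8, 10):
        specs.append(C(f"EWP-{k}", "TFD", timescale.ewp_power, band=k))

    # ----------------------------------------------------------------- FRD
    for name, func in [
        ("FR4", fractal.fr4), ("HFD", fractal.higuchi_fd), ("DFA", fractal.dfa),
        ("AEN", fractal.approximate_entropy),
        ("HJA", fractal.hjorth_activity), ("HJM", fractal.hjorth_mobility),
        ("HJC", fractal.hjorth_complexity),
        ("KFD", fractal.katz_fd), ("PFD", fractal.petrosian_fd),
        ("MFL", fractal.mfl),
    ]:
        specs.append(C(name, "FRD", func))

    # ------------------------------------------------------------------ SD
    for name, func, num, den in [
        ("FEPR", spatial.power_ratio, "flexor", "extensor"),
        ("FEMR", spatial.mav_ratio, "flexor", "extensor"),
        ("FTPR", spatial.power_ratio, "flexor", "thenar"),
        ("FTMR", spatial.mav_ratio, "flexor", "thenar"),
        ("ETPR", spatial.power_ratio, "extensor", "thenar"),
        ("ETMR", spatial.mav_ratio, "extensor", "thenar"),
    ]:
        specs.append(_spatial(name, func, num_role=num, den_role=den))

    return specs


_DEFAULT: FeatureRegistry | None = None


def default_registry() -> FeatureRegistry:
    """The full 127-feature registry (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = FeatureRegistry(_build_specs())
    return _DEFAULT


def load_manifest() -> list[dict]:
    """The packaged manifest listing every feature's name/domain/arity."""
    text = resources.files(__package__).joinpath("manifest.json").read_text()
    return json.loads(text)


#: Compact demo subset (cheap, informative features from every domain) used
#: by desk-scale searches; full 127-feature runs are available behind a flag.
CAPPED_FEATURES = (
    "MAV", "WL", "ZC", "SSC", "RMS", "VAR", "SSI", "IEMG", "WAMP",
    "MMAV5", "LMAV", "MSR", "RSM0", "MHW", "MTW",
    "MNF", "MDF", "MASP",
    "DWT", "EWT-8",
    "HFD", "DFA", "AEN", "FR4",
    "FEPR",
)


@dataclass
class FeatureMatrix:
    """Instances x feature-dimensions table with per-column provenance.

    columns : list of (feature_name, channel, component) triples; spatial
    features use channel = -1.  Two-element tuples are normalized to
    component 0.
    """

    values: np.ndarray
    columns: list[tuple]
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        self.columns = [
            tuple(c) if len(c) == 3 else (c[0], c[1], 0) for c in self.columns
        ]
        n, d = self.values.shape
        if len(self.columns) != d:
            raise RegistryError(f"{len(self.columns)} column labels for {d} columns")
        if self.labels.size != n or self.subjects.size != n:
            raise RegistryError("labels/subjects must align with rows")

    @property
    def feature_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for name, _ch, _i in self.columns:
            seen.setdefault(name, None)
        return tuple(seen)

    def column_indices(self, selection: Iterable[str]) -> np.ndarray:
        wanted = set(selection)
        missing = wanted - set(self.feature_names)
        if missing:
            raise RegistryError(f"features not in matrix: {sorted(missing)}")
        idx = [i for i, (name, _c, _k) in enumerate(self.columns) if name in wanted]
        return np.asarray(idx, dtype=int)

    def select(self, selection: Iterable[str]) -> np.ndarray:
        return self.values[:, self.column_indices(selection)]

    # -- persistence -------------------------------------------------------

    def to_csv(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        header = ",".join(f"{n}@{c}#{k}" for n, c, k in self.columns)
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")
        sidecar = {
            "labels": self.labels.tolist(),
            "subjects": self.subjects.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        from pathlib import Path

        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip().split(",")
        columns = []
        for col in header:
            name, rest = col.rsplit("@", 1)
            ch, k = rest.split("#")
            columns.append((name, int(ch), int(k)))
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, columns=columns,
                   labels=np.asarray(sidecar["labels"]),
                   subjects=np.asarray(sidecar["subjects"]))


def extract_matrix(
    segments: Sequence[Segment],
    registry: FeatureRegistry | None = None,
    selection: Iterable[str] | None = None,
) -> FeatureMatrix:
    """Extract the selected features from every segment.

    Column order is registry order x channel order (spatial features occupy
    one trailing column each, channel -1).  Extraction errors are re-raised
    with the segment index and feature name attached.
    """
    registry = registry or default_registry()
    if selection is None:
        specs = registry.specs
    else:
        names = list(selection)
        if not names:
            raise RegistryError("empty feature selection")
        keep = {registry.resolve(n).name for n in names}
        specs = tuple(s for s in registry.specs if s.name in keep)
    if not specs:
        raise RegistryError("empty feature selection")
    if not segments:
        raise RegistryError("no segments to extract from")
    n_channels = segments[0].window.shape[1]
    if any(s.window.shape[1] != n_channels for s in segments):
        raise RegistryError("segments disagree on channel count")

    columns: list[tuple] = []
    for spec in specs:
        if spec.kind == "spatial":
            columns.extend((spec.name, -1, k) for k in range(spec.arity))
        else:
            for ch in range(n_channels):
                columns.extend((spec.name, ch, k) for k in range(spec.arity))

    rows = np.empty((len(segments), len(columns)))
    for i, seg in enumerate(segments):
        fs = getattr(seg, "fs", 1000.0)
        j = 0
        for spec in specs:
            try:
                if spec.kind == "spatial":
                    vals = np.atleast_1d(
                        np.asarray(spec.func(seg.window, seg.channel_roles), dtype=float)
                    )
                    rows[i, j:j + spec.arity] = vals
                    j += spec.arity
                else:
                    for ch in range(n_channels):
                        vals = np.atleast_1d(
                            np.asarray(spec.func(seg.window[:, ch], fs), dtype=float)
                        )
                        rows[i, j:j + spec.arity] = vals
                        j += spec.arity
            except DegenerateSignalError as exc:
                raise DegenerateSignalError(
                    f"segment {i} ({seg.subject_id}/{seg.label}), feature {spec.name}: {exc}"
                ) from exc
        if not np.all(np.isfinite(rows[i])):
            bad = [columns[k] for k in np.flatnonzero(~np.isfinite(rows[i]))]
            raise DegenerateSignalError(
                f"segment {i}: non-finite values for columns {bad[:5]}"
            )

    return FeatureMatrix(
        values=rows,
        columns=columns,
        labels=np.asarray([s.label for s in segments]),
        subjects=np.asarray([s.subject_id for s in segments]),
    )
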