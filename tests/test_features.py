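"""Feature bank: registry bookkeeping, extractor correctness, invariances."""

import numpy as np
import pytest

import emgsnail as es
from emgsnail.features import timedomain as td
from emgsnail.features import timescale
from emgsnail.features.spatial import mav_ratio, power_ratio

from oracles import CLOSED_FORM, THRESHOLDED, o_higuchi

FS = 1000.0

BEST_SET_ACRONYMS = [
    # winners reported by the searches plus every baseline constituent
    "MMAV5", "SSI", "LSSI", "RSM0", "MSR", "MHW", "MTW", "AR3", "AEN",
    "MLASP", "SMN", "FDD", "STFT", "EWP-6", "EWP-10", "EWT-4", "HHT",
    "SWT", "DWT", "ASM", "EWL", "LCARD", "MASP", "MNP", "CC-R", "FR4",
    "IEMG", "VAR", "RSD1", "RSD2", "WL", "SSC", "SM2", "EWT-6", "EWT-8",
    "EWT-10", "CRD", "PERC2", "SM1", "NSV", "ER", "LMAV",
]


class TestRegistry:
    def test_manifest_counts(self, registry):
        manifest = es.load_manifest()
        assert len(manifest) == 127
        assert sum(1 for e in manifest if e["domain"] == "TD") == 80
        assert len(registry) == 127

    def test_manifest_matches_registry(self, registry):
        assert registry.manifest() == es.load_manifest()

    def test_baseline_features_resolve(self, registry):
        for set_id, names in es.BASELINE_SETS.items():
            for name in names:
                assert name in registry, f"{set_id}: {name}"

    @pytest.mark.parametrize("name", BEST_SET_ACRONYMS)
    def test_reported_acronyms_resolve(self, registry, name):
        assert name in registry

    @pytest.mark.parametrize("alias,canonical", [
        ("AR-4", "AR4"), ("EWT10", "EWT-10"), ("EWP6", "EWP-6"),
        ("cc-r", "CC-R"),
    ])
    def test_alias_resolution(self, registry, alias, canonical):
        assert registry.resolve(alias).name == canonical

    def test_unknown_feature_rejected(self, registry):
        with pytest.raises(es.RegistryError):
            registry.resolve("NOPE")

    def test_duplicate_registration_rejected(self, registry):
        reg = es.FeatureRegistry(list(registry.specs[:5]))
        with pytest.raises(es.RegistryError):
            reg.register(registry.specs[0])


class TestClosedFormOracles:
    """Each closed-form extractor matches a direct-summation oracle."""

    @pytest.mark.parametrize("name", sorted(CLOSED_FORM))
    def test_matches_brute_force(self, registry, name, rng):
        spec = registry.resolve(name)
        oracle = CLOSED_FORM[name]
        for _ in range(100):
            x = rng.standard_normal(rng.integers(30, 80)) * rng.uniform(0.1, 10)
            assert spec.func(x, FS) == pytest.approx(oracle(list(x)), abs=1e-9)

    @pytest.mark.parametrize("name", sorted(THRESHOLDED))
    def test_thresholded_counts_match(self, registry, name, rng):
        func = {"ZC": td.zc, "SSC": td.ssc, "WAMP": td.wamp, "MYOP": td.myop}[name]
        oracle = THRESHOLDED[name]
        for _ in range(100):
            x = rng.standard_normal(60)
            thr = rng.uniform(0, 0.5)
            assert func(x, FS, threshold=thr) == pytest.approx(
                oracle(list(x), thr), abs=1e-9
            )

    @pytest.mark.parametrize(
        "name,x,expected",
        [
            ("MAV", [1, -2, 3], 2.0),
            ("WL", [0, 1, 3, 2], 4.0),
            ("RMS", [3, 4], np.sqrt(12.5)),
            ("SSI", [3, 4], 25.0),
            ("MSR", [4, 9], 2.5),
            ("LSSI", [3, 4], np.log(26.0)),
        ],
    )
    def test_worked_examples(self, registry, name, x, expected):
        assert registry.resolve(name).func(np.asarray(x, float), FS) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zc_ssc_worked_examples(self):
        assert td.zc(np.array([1.0, -1.0, 1.0, -1.0]), FS, threshold=0.0) == 3
        assert td.ssc(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), FS, threshold=0.0) == 3


class TestAutoregressive:
    def test_ar1_recovery(self, rng):
        x = np.zeros(10000)
        e = rng.standard_normal(10000)
        for t in range(1, x.size):
            x[t] = 0.5 * x[t - 1] + e[t]
        coefs = td.ar_coefficients(x, order=1)
        assert coefs[0] == pytest.approx(0.5, abs=0.05)

    def test_white_noise_coefficients_vanish(self, rng):
        coefs = td.ar_coefficients(rng.standard_normal(10000), order=2)
        assert np.all(np.abs(coefs) < 0.05)

    def test_constant_input_degenerate(self):
        with pytest.raises(es.DegenerateSignalError):
            td.ar_coefficients(np.ones(100), order=4)

    def test_cepstral_first_coefficient(self, rng):
        """c1 equals the first AR parameter by the recursion's base case."""
        x = rng.standard_normal(500)
        a = td.ar_coefficients(x, order=4)
        c = td.cepstral_coefficients(x, order=4)
        assert c[0] == pytest.approx(a[0], abs=1e-12)


class TestSpectral:
    def test_pure_tone_mnf_mdf(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        reg = es.default_registry()
        assert reg.resolve("MNF").func(x, FS) == pytest.approx(50.0, abs=2.0)
        assert reg.resolve("MDF").func(x, FS) == pytest.approx(50.0, abs=2.0)

    def test_white_noise_mnf_near_quarter_fs(self, rng):
        x = rng.standard_normal(8192)
        reg = es.default_registry()
        assert reg.resolve("MNF").func(x, FS) == pytest.approx(FS / 4, rel=0.1)

    @pytest.mark.parametrize("name", ["MNF", "MDF", "SEF95", "SENT", "FDD"])
    def test_scale_invariance(self, registry, name, rng):
        x = rng.standard_normal(64)
        f = registry.resolve(name).func
        assert f(5.0 * x, FS) == pytest.approx(f(x, FS), abs=1e-9)

    def test_all_zero_spectrum_degenerate(self):
        with pytest.raises(es.DegenerateSignalError):
            es.default_registry().resolve("MNF").func(np.zeros(64), FS)


class TestTimescale:
    def test_constant_signal_has_no_detail_energy(self):
        x = np.full(64, 3.0)
        energies = timescale.dwt_band_energies(x)
        signal_energy = np.sum(x ** 2)
        assert np.all(energies[1:] < 1e-9 * signal_energy)

    def test_ewp_sums_to_one(self, rng):
        _, powers = timescale.ewt_band_powers(rng.standard_normal(64), FS)
        assert powers.sum() == pytest.approx(1.0, abs=1e-6)

    def test_band_limited_noise_avoids_lowest_band(self, rng):
        """Periodogram cross-check: 20-300 Hz noise leaves the lowest
        empirical-wavelet band nearly empty."""
        from scipy import signal as sps

        sos = sps.butter(4, (20, 300), btype="bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(4096))
        energies, powers = timescale.ewt_band_powers(x, FS)
        assert powers[0] < 0.05
        # band powers agree with direct periodogram band integration
        f, p = sps.periodogram(x, fs=FS)
        edges = timescale.ewt_band_edges(FS)
        direct = np.array([
            p[(f > edges[k]) & (f <= edges[k + 1])].sum()
            for k in range(len(edges) - 1)
        ])
        direct[0] += p[f == 0].sum()
        np.testing.assert_allclose(direct / direct.sum(), powers, atol=0.05)

    def test_emd_imfs_reconstruct_most_energy(self, rng):
        x = np.sin(2 * np.pi * 30 * np.arange(256) / FS) + 0.3 * rng.standard_normal(256)
        imfs = timescale.emd(x)
        assert imfs
        recon = np.sum(imfs, axis=0)
        resid = x - recon
        assert np.sum(resid ** 2) < np.sum(x ** 2)

    def test_hht_frequency_tracks_tone(self):
        x = np.sin(2 * np.pi * 80.0 * np.arange(512) / FS)
        assert timescale.hht_feature(x, FS) == pytest.approx(80.0, rel=0.15)


class TestFractal:
    def test_straight_line_dimension_one(self, registry):
        line = np.linspace(0.0, 1.0, 200)
        assert registry.resolve("HFD").func(line, FS) == pytest.approx(1.0, abs=0.05)

    def test_higuchi_matches_loop_oracle(self, registry, rng):
        x = rng.standard_normal(120)
        assert registry.resolve("HFD").func(x, FS) == pytest.approx(
            o_higuchi(list(x), kmax=8), abs=1e-9
        )

    def test_dfa_white_noise_exponent(self, rng):
        assert es.default_registry().resolve("DFA").func(
            rng.standard_normal(4096), FS
        ) == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("name", ["HFD", "DFA", "AEN", "HJM", "HJC", "PFD"])
    def test_scale_invariance(self, registry, name, rng):
        x = rng.standard_normal(128)
        f = registry.resolve(name).func
        assert f(7.0 * x, FS) == pytest.approx(f(x, FS), abs=1e-9)


class TestScaleBehaviour:
    """Amplitude-equivariance table asserted programmatically."""

    LINEAR = ["MAV", "IEMG", "RMS", "WL", "MMAV5", "MEDA", "MAXA", "RSM0"]
    INVARIANT = ["ZC", "SSC", "MNF", "MDF", "HFD", "DFA", "MYOP", "CREST"]

    @pytest.mark.parametrize("name", LINEAR)
    def test_linear_scaling(self, registry, name, rng):
        x = rng.standard_normal(64)
        f = registry.resolve(name).func
        assert f(3.0 * x, FS) == pytest.approx(3.0 * f(x, FS), rel=1e-9)

    @pytest.mark.parametrize("name", INVARIANT)
    def test_scale_invariant(self, registry, name, rng):
        x = rng.standard_normal(64)
        f = registry.resolve(name).func
        assert f(3.0 * x, FS) == pytest.approx(f(x, FS), abs=1e-9)


class TestSpatial:
    ROLES = ("flexor", "flexor", "extensor", "extensor", "thenar")

    def test_identical_channels_unit_ratio(self, rng):
        w = np.tile(rng.standard_normal(60)[:, None], (1, 5))
        assert power_ratio(w, self.ROLES, "flexor", "extensor") == pytest.approx(1.0, abs=1e-9)
        assert mav_ratio(w, self.ROLES, "flexor", "extensor") == pytest.approx(1.0, abs=1e-9)

    def test_silent_group_guarded_finite(self, rng):
        w = np.zeros((60, 5))
        w[:, :2] = rng.standard_normal((60, 2))
        r = power_ratio(w, self.ROLES, "flexor", "extensor")
        assert np.isfinite(r) and r > 1e6

    def test_doubling_flexor_doubles_mav_ratio(self, rng):
        w = rng.standard_normal((60, 5))
        base = mav_ratio(w, self.ROLES, "flexor", "extensor")
        w2 = w.copy()
        w2[:, :2] *= 2.0
        assert mav_ratio(w2, self.ROLES, "flexor", "extensor") == pytest.approx(
            2.0 * base, rel=1e-6
        )

    def test_missing_role_rejected(self, rng):
        w = rng.standard_normal((60, 2))
        with pytest.raises(es.ConfigurationError):
            power_ratio(w, ("flexor", "flexor"), "flexor", "extensor")


class TestLogVariant:
    def test_zero_maps_to_zero(self, registry):
        spec = registry.resolve("MEAN")
        logged = es.log_variant(spec, name="LMEAN_TEST")
        assert logged.func(np.array([1.0, -1.0]), FS) == 0.0

    def test_monotone(self, registry):
        spec = registry.resolve("SSI")
        logged = es.log_variant(spec, name="LSSI_TEST")
        small = logged.func(np.array([1.0, 1.0]), FS)
        large = logged.func(np.array([5.0, 5.0]), FS)
        assert small < large


class TestExtractMatrix:
    def test_small_selection_shape(self, separable_segments):
        m = es.extract_matrix(separable_segments[:10], selection=["MAV", "WL"])
        assert m.values.shape == (10, 10)  # 2 features x 5 channels
        assert m.feature_names == ("MAV", "WL")

    def test_empty_selection_rejected(self, separable_segments):
        with pytest.raises(es.RegistryError):
            es.extract_matrix(separable_segments[:2], selection=[])

    def test_full_registry_column_bookkeeping(self, registry, separable_segments):
        """Column count equals sum of arities x channels, per the manifest."""
        m = es.extract_matrix(separable_segments[:3])
        manifest = es.load_manifest()
        expected = sum(
            e["arity"] * (1 if e["kind"] == "spatial" else 5) for e in manifest
        )
        assert m.values.shape == (3, expected)
        assert np.all(np.isfinite(m.values))

    def test_error_names_segment_and_feature(self):
        seg = es.Segment(window=np.random.default_rng(0).standard_normal((4, 2)),
                         label="fist", subject_id="S01", onset_index=0,
                         channel_roles=("flexor", "extensor"))
        with pytest.raises(es.DegenerateSignalError, match="MNF"):
            es.extract_matrix([seg], selection=["MNF"])

    def test_csv_roundtrip(self, tmp_path, separable_segments):
        m = es.extract_matrix(separable_segments[:5], selection=["MAV", "FEPR"])
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        back = es.FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-12)
        assert back.columns == m.columns
        assert list(back.labels) == list(m.labels)
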