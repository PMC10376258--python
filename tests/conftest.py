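import numpy as np
import pytest

import emgsnail as es


@pytest.fixture(scope="session")
def separable_dataset():
    """Small fully-separable dataset: severity 1, no crosstalk, equal gains."""
    cfg = es.SynthConfig(
        n_subjects=6, reps_per_gesture=3, subject_gain_sd=0.0,
        crosstalk=0.0, severity=1.0, seed=1,
    )
    return es.generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_segments(separable_dataset):
    return es.segments_from_annotations(separable_dataset)


@pytest.fixture(scope="session")
def amplitude_matrix(separable_segments):
    """Envelope-amplitude features only (MAV, RMS) on the separable data."""
    return es.extract_matrix(separable_segments, selection=["MAV", "RMS"])


@pytest.fixture(scope="session")
def planted_matrix():
    """5 informative + 20 noise features, 12 subjects x 7 classes x 3 reps."""
    return es.planted_feature_matrix(seed=1)


@pytest.fixture(scope="session")
def fast_protocol():
    return es.EvalProtocol(n_iterations=10, seed=7)


@pytest.fixture(scope="session")
def registry():
    return es.default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
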