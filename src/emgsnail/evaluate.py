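"""Subject-wise repeated cross-validation with an SVM backend.

The score used everywhere in the search is the mean correct classification
rate (CCR, in percent) over repeated random subject-wise holdouts: at each
iteration a fixed fraction of the participants (2 of 19 at the default 0.1)
is held out entirely, the classifier is trained on the remaining subjects'
segments, and CCR is measured on the held-out subjects.  Holding out whole
subjects prevents within-subject leakage and measures subject-independent
generalization.

Split seeds derive only from (protocol seed, iteration index), never from
the candidate feature set, so every candidate is scored on the same
partitions and candidate rankings are paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import ProtocolError
from .features import FeatureMatrix

MAX_REDRAWS = 50


@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validation protocol parameters."""

    test_fraction: float = 0.1
    n_iterations: int = 100
    kernel: str = "linear"
    C: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 0.5:
            raise ProtocolError("test_fraction must be in (0, 0.5)")
        if self.n_iterations < 1:
            raise ProtocolError("n_iterations must be >= 1")


@dataclass
class EvaluationResult:
    """Mean/SD CCR (percent) over the protocol's iterations."""

    mean_ccr: float
    sd_ccr: float
    per_iteration_ccr: list[float]
    n_iterations: int

    @classmethod
    def from_iterations(cls, ccrs: Sequence[float]) -> "EvaluationResult":
        arr = np.asarray(ccrs, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return cls(mean_ccr=float(np.mean(arr)), sd_ccr=sd,
                   per_iteration_ccr=[float(v) for v in arr],
                   n_iterations=int(arr.size))

    def to_dict(self) -> dict:
        return {
            "mean_ccr": self.mean_ccr,
            "sd_ccr": self.sd_ccr,
            "n_iterations": self.n_iterations,
        }


def ccr(predicted: Sequence, truth: Sequence) -> float:
    """Correct classification rate in percent."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0 or predicted.size != truth.size:
        raise ProtocolError("predicted/truth must be equal-length and non-empty")
    return float(100.0 * np.count_nonzero(predicted == truth) / truth.size)


def split_subjects(
    subject_ids: Iterable, test_fraction: float, rng: np.random.Generator
) -> tuple[set, set]:
    """Random disjoint exhaustive train/test partition by subject.

    Test size is max(1, round(n * test_fraction)), so 19 subjects at the
    default fraction 0.1 hold out 2 participants.
    """
    subjects = sorted(set(subject_ids))
    n = len(subjects)
    if n < 3:
        raise ProtocolError(f"need >= 3 distinct subjects, got {n}")
    n_test = max(1, int(np.floor(n * test_fraction + 0.5)))
    test = set(rng.choice(subjects, size=n_test, replace=False).tolist())
    train = set(subjects) - test
    return train, test


def _iteration_rng(seed: int, iteration: int, redraw: int = 0) -> np.random.Generator:
    return np.random.default_rng((seed, iteration, redraw))


def evaluate(
    matrix: FeatureMatrix,
    selection: Iterable[str],
    protocol: EvalProtocol = EvalProtocol(),
    split_hook: Callable[[dict], None] | None = None,
) -> EvaluationResult:
    """Score a feature selection by repeated subject-wise holdout.

    Per iteration: draw a subject split, standardize columns on training
    statistics only, fit a soft-margin SVM (one-vs-one multiclass), and
    measure CCR on the held-out subjects' rows.  Iterations whose training
    fold misses a class are redrawn (bounded).  ``split_hook``, when given,
    receives per-iteration details (train/test subjects, scaler statistics)
    for leakage instrumentation.
    """
    selection = list(selection)
    if not selection:
        raise ProtocolError("empty feature selection")
    X_all = matrix.select(selection)
    y = matrix.labels
    subjects = matrix.subjects
    classes = np.unique(y)
    if classes.size < 2:
        raise ProtocolError("need >= 2 classes")

    ccrs = np.empty(protocol.n_iterations)
    for i in range(protocol.n_iterations):
        for redraw in range(MAX_REDRAWS):
            rng = _iteration_rng(protocol.seed, i, redraw)
            train_subj, test_subj = split_subjects(
                subjects, protocol.test_fraction, rng
            )
            train_mask = np.isin(subjects, sorted(train_subj))
            if np.unique(y[train_mask]).size == classes.size:
                break
        else:
            raise ProtocolError(
                f"iteration {i}: no class-complete training fold in {MAX_REDRAWS} redraws"
            )
        test_mask = ~train_mask

        X_train = X_all[train_mask]
        X_test = X_all[test_mask]
        if protocol.standardize:
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0  # constant columns pass through centred
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd
        else:
            mu = sd = None

        clf = SVC(kernel=protocol.kernel, C=protocol.C,
                  decision_function_shape="ovo")
        clf.fit(X_train, y[train_mask])
        predicted = clf.predict(X_test)
        ccrs[i] = ccr(predicted, y[test_mask])

        if split_hook is not None:
            split_hook(
                {
                    "iteration": i,
                    "train_subjects": set(train_subj),
                    "test_subjects": set(test_subj),
                    "scaler_mean": mu,
                    "scaler_sd": sd,
                    "train_rows": np.flatnonzero(train_mask),
                    "test_rows": np.flatnonzero(test_mask),
                }
            )

    return EvaluationResult.from_iterations(ccrs)
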