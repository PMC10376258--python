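"""Canonical multi-feature baseline sets (MFS1-8) and the comparison harness.

The eight baselines are the canonical myoelectric feature sets from the
pattern-recognition literature (Hudgins' TD-4, TD-AR, TD-NLS, Du's set,
NTDFS, TD-DFA, Oskoei & Hu's set, Wang's set).  The harness evaluates every
set under one shared protocol and tests whether the best empirical set
outperforms each of the others with a one-tailed unpaired pooled-variance
t-test (DF = n1 + n2 - 2, so two 100-iteration runs give DF = 198).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ProtocolError, RegistryError
from .evaluate import EvalProtocol, EvaluationResult, evaluate
from .bfs import CandidateSet
from .features import FeatureMatrix, FeatureRegistry, default_registry

#: Canonical baseline sets, id -> feature names.
BASELINE_SETS: dict[str, tuple[str, ...]] = {
    "MFS1": ("MAV", "WL", "ZC", "SSC"),
    "MFS2": ("RMS", "AR6"),
    "MFS3": ("LMAV", "NSV"),
    "MFS4": ("IEMG", "VAR", "WL", "ZC", "SSC", "WAMP"),
    "MFS5": ("SSI", "RSD1", "RSD2", "MSR", "ASM", "ROG"),
    "MFS6": ("ZC", "SSC", "AR4", "PSR", "DFA", "HFD"),
    "MFS7": ("MAV", "RMS", "WL", "VAR", "ZC", "SSC", "WAMP", "MMAV1",
             "MMAV2", "PSP", "AR2", "AR5", "MDF", "MNF"),
    "MFS8": ("MAV", "VAR", "AR4", "ZC", "MNF", "MDF"),
}

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class BaselineSet:
    id: str
    features: tuple[str, ...]


def baseline_sets(registry: FeatureRegistry | None = None) -> list[BaselineSet]:
    """The MFS1-8 baselines, validated against the registry."""
    registry = registry or default_registry()
    out = []
    for set_id, names in BASELINE_SETS.items():
        for name in names:
            if name not in registry:
                raise ConfigurationError(
                    f"{set_id}: feature {name!r} not in registry"
                )
        out.append(BaselineSet(id=set_id, features=names))
    return out


def t_test_one_tailed(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, int, float]:
    """One-tailed unpaired pooled-variance t-test for mean(a) > mean(b).

    Returns (t, DF, p) with DF = n1 + n2 - 2.  Zero pooled variance with
    equal means degenerates to (0, DF, 0.5); with unequal means p goes to
    its 0/1 limit.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ProtocolError("each group needs >= 2 observations")
    df = int(a.size + b.size - 2)
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 0.5
        return (np.inf, df, 0.0) if np.mean(a) > np.mean(b) else (-np.inf, df, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(t), df, float(p)


def significance_stars(p: float) -> str:
    stars = sum(p < level for level in SIGNIFICANCE_LEVELS)
    return "*" * stars


def compare_all(
    matrix: FeatureMatrix,
    best_sets: Sequence[CandidateSet],
    baselines: Sequence[BaselineSet] | None = None,
    protocol: EvalProtocol = EvalProtocol(),
    registry: FeatureRegistry | None = None,
) -> pd.DataFrame:
    """Evaluate empirical winners and baselines under one shared protocol.

    The first of ``best_sets`` (the spiral winner by convention) is the
    reference row; every other row is tested against it with the one-tailed
    unpaired t-test.  Returns the comparison table with CCR mean/SD, DF,
    p-value and significance stars per row.
    """
    if not best_sets:
        raise ProtocolError("need at least one empirical best set")
    registry = registry or default_registry()
    if baselines is None:
        baselines = baseline_sets(registry)

    rows: list[dict] = []
    results: list[EvaluationResult] = []
    labels: list[str] = []
    for i, cand in enumerate(best_sets):
        label = "Best of SBFS" if i == 0 else f"Best set {i + 1}"
        res = cand.result or evaluate(matrix, cand.features, protocol)
        labels.append(label)
        results.append(res)
        rows.append({"feature_set": label,
                     "features": "|".join(cand.features)})
    for base in baselines:
        # resolve aliases through the registry where possible; matrix-local
        # names (e.g. synthetic planted features) pass through unchanged
        selection = []
        for f in base.features:
            try:
                selection.append(registry.resolve(f).name)
            except RegistryError:
                selection.append(f)
        missing = [f for f in selection if f not in matrix.feature_names]
        if missing:
            raise ConfigurationError(
                f"{base.id}: features {missing} absent from matrix"
            )
        res = evaluate(matrix, selection, protocol)
        labels.append(base.id)
        results.append(res)
        rows.append({"feature_set": base.id, "features": "|".join(base.features)})

    reference = results[0]
    for row, res in zip(rows, results):
        row["mean_ccr"] = res.mean_ccr
        row["sd_ccr"] = res.sd_ccr
        if res is reference:
            row.update({"df": None, "t": None, "p_value": None, "stars": ""})
        else:
            t, df, p = t_test_one_tailed(
                reference.per_iteration_ccr, res.per_iteration_ccr
            )
            row.update({"df": df, "t": t, "p_value": p,
                        "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def all_features_baseline(
    matrix: FeatureMatrix,
    protocol: EvalProtocol = EvalProtocol(),
) -> EvaluationResult:
    """Evaluate the full concatenation of every extracted feature at once,
    the redundancy-prone control condition for the searches."""
    return evaluate(matrix, list(matrix.feature_names), protocol)
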