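"""Exhaustive brute-force enumeration and ranking of feature combinations.

All feature sets of size r = 1..4 are enumerated (C(n, r) candidates, so
127 features yield 8001 pairs, 333 375 triples and 10 334 625 tetra sets),
scored by the subject-wise SVM evaluator, and ranked by mean CCR with a
deterministic tie-break (mean CCR desc, SD asc, lexicographic names).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ProtocolError
from .evaluate import EvalProtocol, EvaluationResult, evaluate
from .features import FeatureMatrix


@dataclass
class CandidateSet:
    """An unordered feature-name set with its cross-validated score."""

    features: tuple[str, ...]
    result: EvaluationResult | None = None

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features))
        if len(set(feats)) != len(feats):
            raise ProtocolError(f"duplicate features in candidate {feats}")
        self.features = feats

    @property
    def r(self) -> int:
        return len(self.features)

    @property
    def mean_ccr(self) -> float:
        return self.result.mean_ccr if self.result else float("nan")

    @property
    def sd_ccr(self) -> float:
        return self.result.sd_ccr if self.result else float("nan")

    def sort_key(self):
        return (-self.mean_ccr, self.sd_ccr, self.features)


@dataclass
class RankedPool:
    """Candidates sorted by (mean CCR desc, SD asc, lexicographic names)."""

    candidates: list[CandidateSet] = field(default_factory=list)

    @classmethod
    def from_candidates(cls, candidates: Iterable[CandidateSet]) -> "RankedPool":
        unique: dict[tuple, CandidateSet] = {}
        for cand in candidates:
            unique.setdefault(cand.features, cand)
        return cls(sorted(unique.values(), key=CandidateSet.sort_key))

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __getitem__(self, item):
        return self.candidates[item]

    @property
    def best(self) -> CandidateSet:
        return self.candidates[0]

    def feature_union(self) -> set[str]:
        out: set[str] = set()
        for cand in self.candidates:
            out.update(cand.features)
        return out


def count_combinations(n: int, r: int) -> int:
    """C(n, r), the brute-force search size at concatenation level r."""
    return math.comb(n, r)


def enumerate_feature_tuples(names: Sequence[str], r: int) -> Iterator[tuple]:
    """Stream all size-r feature-name tuples in canonical sorted-name form.

    Lightweight counterpart of :func:`enumerate_combinations` for exhaustive
    counting (tens of millions of tetra sets stream in seconds).
    """
    if not 1 <= r <= len(names):
        raise ProtocolError(f"r={r} out of range for {len(names)} features")
    return combinations(sorted(names), r)


def enumerate_combinations(names: Sequence[str], r: int) -> Iterator[CandidateSet]:
    """Stream all size-r feature sets in canonical sorted-name form."""
    for combo in enumerate_feature_tuples(names, r):
        yield CandidateSet(features=combo)


def run_bfs(
    matrix: FeatureMatrix,
    names: Sequence[str] | None = None,
    r_max: int = 2,
    protocol: EvalProtocol = EvalProtocol(),
    checkpoint_dir: str | Path | None = None,
    cache: dict | None = None,
) -> dict[int, RankedPool]:
    """Score every combination of size 1..r_max and rank each level.

    With ``checkpoint_dir`` set, scored candidates are appended to a JSONL
    file per level as they finish, and an interrupted run resumes without
    rescoring.  ``cache`` (features-tuple -> EvaluationResult) is shared with
    the spiral search so brute-force scores are inherited, not recomputed.
    """
    if not 1 <= r_max <= 4:
        raise ProtocolError("r_max must be in 1..4")
    names = list(names) if names is not None else list(matrix.feature_names)
    cache = cache if cache is not None else {}

    pools: dict[int, RankedPool] = {}
    for r in range(1, r_max + 1):
        done: dict[tuple, EvaluationResult] = {}
        ckpt = None
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir) / f"bfs{r}.jsonl"
            ckpt.parent.mkdir(parents=True, exist_ok=True)
            if ckpt.exists():
                for line in ckpt.read_text().splitlines():
                    rec = json.loads(line)
                    done[tuple(rec["features"])] = EvaluationResult(
                        mean_ccr=rec["mean_ccr"], sd_ccr=rec["sd_ccr"],
                        per_iteration_ccr=rec.get("per_iteration_ccr", []),
                        n_iterations=rec["n_iterations"],
                    )
        scored: list[CandidateSet] = []
        fh = ckpt.open("a") if ckpt is not None else None
        try:
            for cand in enumerate_combinations(names, r):
                if cand.features in done:
                    cand.result = done[cand.features]
                elif cand.features in cache:
                    cand.result = cache[cand.features]
                else:
                    cand.result = evaluate(matrix, cand.features, protocol)
                    if fh is not None:
                        fh.write(json.dumps({
                            "features": list(cand.features),
                            "mean_ccr": cand.result.mean_ccr,
                            "sd_ccr": cand.result.sd_ccr,
                            "per_iteration_ccr": cand.result.per_iteration_ccr,
                            "n_iterations": cand.result.n_iterations,
                        }) + "\n")
                        fh.flush()
                cache[cand.features] = cand.result
                scored.append(cand)
        finally:
            if fh is not None:
                fh.close()
        pools[r] = RankedPool.from_candidates(scored)
    return pools


def top_quintile(pool: RankedPool) -> RankedPool:
    """The near-to-top quintile: the first ceil(0.2 * |pool|) candidates."""
    if not len(pool):
        raise ProtocolError("empty pool")
    keep = math.ceil(0.2 * len(pool))
    return RankedPool(candidates=list(pool.candidates[:keep]))


def domain_distribution(pool: RankedPool, registry) -> dict[str, float]:
    """Proportion of candidates per domain combination (e.g. 'TD', 'TD+FD')."""
    counts: dict[str, int] = {}
    for cand in pool:
        domains = sorted({registry.domain_of(f) for f in cand.features})
        key = "+".join(domains)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def linkage_trace(
    pools: dict[int, RankedPool], top_k: int = 50
) -> list[dict]:
    """Superset lineage edges between consecutive levels' top-k candidates."""
    if len(pools) < 2:
        raise ProtocolError("need >= 2 pools to trace lineage")
    edges: list[dict] = []
    levels = sorted(pools)
    for r0, r1 in zip(levels, levels[1:]):
        tops0 = pools[r0].candidates[:top_k]
        tops1 = pools[r1].candidates[:top_k]
        for parent in tops0:
            pset = set(parent.features)
            for child in tops1:
                if pset < set(child.features):
                    edges.append({
                        "parent": list(parent.features),
                        "child": list(child.features),
                        "from_r": r0,
                        "to_r": r1,
                    })
    return edges


def save_pool_csv(pool: RankedPool, path: str | Path) -> None:
    """Persist a ranked pool as CSV (features, mean_ccr, sd_ccr)."""
    import pandas as pd

    rows = [
        {"features": "|".join(c.features), "mean_ccr": c.mean_ccr, "sd_ccr": c.sd_ccr}
        for c in pool
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
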