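"""SNAiL: semi-brute-force navigated amalgamation in linkage.

The spiral search grows feature sets one feature per stage, from the
top-quintile seeds of the brute-force pools up to 20 features, using the
golden ratio phi = 1.618 as the magnification/truncation factor throughout:

* parents per stage  = top max(2, round(|pool| / phi)) sets,
* candidates         = parent union {one new feature}, capped at
  ceil(phi * |pool|) in parent-rank order,
* surviving pool     = top ceil(|candidates| / phi) candidates.

The search stops at the maximum size or earlier, when the best mean CCR has
stopped improving for `patience` consecutive stages — the deferred
overfitting criterion.  Scores are cached by feature set, so brute-force
seeds inherit their scores and re-proposed sets are never re-evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError, SearchExhausted
from .evaluate import EvalProtocol, evaluate
from .bfs import CandidateSet, RankedPool, top_quintile
from .features import FeatureMatrix

PHI = 1.618


@dataclass(frozen=True)
class SnailConfig:
    """Spiral-search configuration."""

    phi: float = PHI
    min_size: int = 5
    max_size: int = 20
    source_depth: int = 2
    patience: int = 2
    protocol: EvalProtocol = field(default_factory=EvalProtocol)

    def __post_init__(self) -> None:
        if not self.phi > 1:
            raise ProtocolError("phi must be > 1")
        if not 1 <= self.source_depth <= 4:
            raise ProtocolError("source_depth must be in 1..4")
        if not (self.source_depth < self.min_size <= self.max_size <= 20):
            raise ProtocolError(
                "need source_depth < min_size <= max_size <= 20"
            )
        if self.min_size < 5:
            raise ProtocolError("min_size must be >= 5")
        if self.patience < 1:
            raise ProtocolError("patience must be >= 1")


@dataclass
class StageReport:
    size: int
    n_candidates: int
    best: CandidateSet
    pool: RankedPool

    def to_dict(self) -> dict:
        return {
            "stage": self.size,
            "n_candidates": self.n_candidates,
            "best_set": list(self.best.features),
            "mean_ccr": self.best.mean_ccr,
            "sd_ccr": self.best.sd_ccr,
        }


@dataclass
class SnailResult:
    """Final state of a spiral run: per-stage reports and the overall winner."""

    stages: list[StageReport]
    best_overall: CandidateSet
    stopped_early: bool

    @property
    def history(self) -> list[float]:
        return [s.best.mean_ccr for s in self.stages]

    def best_at_size(self, size: int) -> CandidateSet:
        for stage in self.stages:
            if stage.size == size:
                return stage.best
        raise KeyError(f"no stage of size {size}")


def seed_pool(bfs_pools: dict[int, RankedPool], cfg: SnailConfig) -> RankedPool:
    """Union of the top-quintile candidates of each sourced brute-force pool."""
    available = [r for r in sorted(bfs_pools) if r <= cfg.source_depth]
    if not available:
        raise ProtocolError(
            f"no brute-force pools at depth <= {cfg.source_depth}"
        )
    seeds: list[CandidateSet] = []
    for r in available:
        if not len(bfs_pools[r]):
            raise ProtocolError(f"brute-force pool r={r} is empty")
        seeds.extend(top_quintile(bfs_pools[r]).candidates)
    return RankedPool.from_candidates(seeds)


def n_parents(pool_size: int, phi: float) -> int:
    """Parent count per stage: top max(2, round(pool/phi)) sets."""
    return max(2, int(np.floor(pool_size / phi + 0.5)))


def candidate_cap(pool_size: int, phi: float) -> int:
    return math.ceil(phi * pool_size)


def pool_truncation(n_candidates: int, phi: float) -> int:
    """Surviving pool size after a stage: ceil(candidates/phi)."""
    return math.ceil(n_candidates / phi)


def propose_candidates(
    pool: RankedPool,
    seeds: RankedPool,
    cfg: SnailConfig,
    target_size: int,
) -> list[CandidateSet]:
    """Grow size-(target_size) candidates from the ranked pool.

    Parents are the top sets of size target_size - 1; the extension alphabet
    is every feature appearing in the seed pool or in a parent.  Candidates
    are deduplicated canonically and capped at ceil(phi * |pool|) in
    parent-rank order.
    """
    if not len(pool):
        raise ProtocolError("empty pool")
    eligible = [c for c in pool if c.r == target_size - 1]
    if not eligible:
        raise SearchExhausted(
            f"no size-{target_size - 1} parents available in pool"
        )
    parents = eligible[: n_parents(len(pool), cfg.phi)]
    alphabet = sorted(seeds.feature_union() | {f for p in parents for f in p.features})

    cap = candidate_cap(len(pool), cfg.phi)
    proposed: list[CandidateSet] = []
    seen: set[tuple] = set()
    for parent in parents:
        pset = set(parent.features)
        for f in alphabet:
            if f in pset:
                continue
            features = tuple(sorted(pset | {f}))
            if features in seen:
                continue
            seen.add(features)
            proposed.append(CandidateSet(features=features))
            if len(proposed) >= cap:
                break
        if len(proposed) >= cap:
            break
    if not proposed:
        raise SearchExhausted("extension alphabet exhausted")
    return proposed


def run_snail(
    matrix: FeatureMatrix,
    bfs_pools: dict[int, RankedPool],
    cfg: SnailConfig = SnailConfig(),
    cache: dict | None = None,
) -> SnailResult:
    """Run the spiral amalgamation from brute-force seeds.

    Stages target sizes source_depth+1 .. max_size; the per-stage best and
    the running best are recorded, and the kept-best winner is therefore
    monotone non-decreasing across stages.  Fully deterministic given the
    protocol seed.
    """
    cache = cache if cache is not None else {}
    seeds = seed_pool(bfs_pools, cfg)
    for cand in seeds:
        if cand.result is not None:
            cache.setdefault(cand.features, cand.result)

    pool = seeds
    stages: list[StageReport] = []
    best_overall: CandidateSet | None = None
    stalls = 0
    stopped_early = False

    for size in range(cfg.source_depth + 1, cfg.max_size + 1):
        try:
            proposed = propose_candidates(pool, seeds, cfg, target_size=size)
        except SearchExhausted:
            stopped_early = True
            break
        for cand in proposed:
            if cand.features in cache:
                cand.result = cache[cand.features]
            else:
                cand.result = evaluate(matrix, cand.features, cfg.protocol)
                cache[cand.features] = cand.result
        ranked = RankedPool.from_candidates(proposed)
        keep = pool_truncation(len(ranked), cfg.phi)
        pool = RankedPool(candidates=list(ranked.candidates[:keep]))
        stage = StageReport(size=size, n_candidates=len(ranked),
                            best=ranked.best, pool=pool)
        stages.append(stage)

        if size >= cfg.min_size:
            if best_overall is None or stage.best.mean_ccr > best_overall.mean_ccr:
                best_overall = stage.best
                stalls = 0
            else:
                stalls += 1
                if stalls >= cfg.patience:
                    stopped_early = True
                    break

    if best_overall is None:
        # search exhausted before min_size: fall back to the best stage seen
        pool_best = max(
            (s.best for s in stages), key=lambda c: c.mean_ccr, default=None
        )
        if pool_best is None:
            raise SearchExhausted("spiral search produced no candidates")
        best_overall = pool_best

    return SnailResult(stages=stages, best_overall=best_overall,
                       stopped_early=stopped_early)


def jaccard(a, b) -> float:
    """Jaccard overlap between two feature sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compare_sources(
    matrix: FeatureMatrix,
    bfs_pools: dict[int, RankedPool],
    cfg: SnailConfig = SnailConfig(),
    depths: tuple[int, ...] = (2, 3, 4),
    cache: dict | None = None,
) -> dict:
    """Run the spiral per brute-force source depth and compare the winners.

    Reports per-depth best mean CCR / SD and pairwise Jaccard overlap of the
    winning feature sets, all under identical protocol seeds.
    """
    from dataclasses import replace

    cache = cache if cache is not None else {}
    available = set(bfs_pools)
    runs: dict[int, SnailResult] = {}
    for depth in depths:
        if depth not in available:
            continue
        cfg_d = replace(cfg, source_depth=depth)
        runs[depth] = run_snail(matrix, bfs_pools, cfg_d, cache=cache)
    if not runs:
        raise ProtocolError("no usable source depths")

    overlap = {
        f"{a}x{b}": jaccard(runs[a].best_overall.features,
                            runs[b].best_overall.features)
        for a in runs
        for b in runs
        if a < b
    }
    return {
        "per_depth": {
            d: {
                "best_set": list(r.best_overall.features),
                "mean_ccr": r.best_overall.mean_ccr,
                "sd_ccr": r.best_overall.sd_ccr,
                "n_stages": len(r.stages),
            }
            for d, r in runs.items()
        },
        "jaccard": overlap,
        "runs": runs,
    }
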