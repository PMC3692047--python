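"""Benchmark protocol: intersection-restricted ROC curves, AUC and TPR at a cutoff.

Rankings are compared on the genes scored by every method under comparison;
positive and negative genes' ranks serve as scores. The AUC is the
Mann–Whitney probability that a random positive outranks a random negative,
with ties counted 1/2, and the ROC curve is built by sweeping the rank
threshold so its trapezoidal area equals that probability exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.stats import rankdata

from .core import GeneUniverse
from .integrate import MetaRankTable

RankMapping = Mapping[str, float]
Ranking = Union[RankMapping, MetaRankTable]


@dataclass
class BenchmarkSets:
    """Positive and negative benchmark genes, with optional exclusions.

    Exclusions (e.g. genes used to build an evidence layer) are removed from
    the negatives before validation, mirroring the protocol of sampling
    negatives that overlap no training set.
    """

    positives: set[str]
    negatives: set[str]
    exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.positives = set(self.positives)
        self.negatives = set(self.negatives) - set(self.exclusions)
        self.exclusions = set(self.exclusions)
        if self.positives & self.negatives:
            overlap = sorted(self.positives & self.negatives)
            raise ValueError(f"positives and negatives overlap: {overlap[:5]}")


@dataclass
class RocResult:
    """ROC curve points from (0,0) to (1,1) plus the trapezoidal AUC."""

    points: np.ndarray  # shape (k, 2): columns FPR, TPR
    auc: float
    n_pos: int
    n_neg: int


def _as_rank_mapping(ranking: Ranking) -> dict[str, float]:
    if isinstance(ranking, MetaRankTable):
        return {g: float(r) for g, r in ranking.rank_mapping().items()}
    return {g: float(r) for g, r in ranking.items()}


def restrict_to_common_universe(
    rankings: Sequence[Ranking],
    sets: BenchmarkSets,
) -> tuple[BenchmarkSets, list[dict[str, float]]]:
    """Confine the benchmark to genes scored in every ranking.

    Returns the filtered benchmark sets and each ranking restricted to the
    common gene universe. An empty intersection for either class is an error.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    maps = [_as_rank_mapping(r) for r in rankings]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    positives = sets.positives & common
    negatives = sets.negatives & common
    if not positives:
        raise ValueError("no positive gene is scored in every ranking")
    if not negatives:
        raise ValueError("no negative gene is scored in every ranking")
    filtered = BenchmarkSets(
        positives=positives, negatives=negatives, exclusions=set(sets.exclusions)
    )
    restricted = [{g: m[g] for g in common} for m in maps]
    return filtered, restricted


def roc_auc_from_ranks(ranks: RankMapping, sets: BenchmarkSets) -> RocResult:
    """ROC curve and AUC from gene ranks (smaller rank = better).

    AUC = P(rank_pos < rank_neg) + ½ P(rank_pos = rank_neg) over all
    positive × negative pairs (the Mann–Whitney statistic); the curve sweeps
    the rank threshold over tied groups, so its trapezoidal area equals the
    AUC exactly.
    """
    if not sets.positives:
        raise ValueError("empty positive set")
    if not sets.negatives:
        raise ValueError("empty negative set")
    missing = (sets.positives | sets.negatives) - set(ranks)
    if missing:
        raise KeyError(f"benchmark genes without a rank: {sorted(missing)[:5]}")
    pos = np.array([ranks[g] for g in sorted(sets.positives)], dtype=float)
    neg = np.array([ranks[g] for g in sorted(sets.negatives)], dtype=float)
    n_pos, n_neg = len(pos), len(neg)

    combined = np.concatenate([pos, neg])
    r = rankdata(combined, method="average")
    # pairs where the positive ranks worse than the negative (+ half-ties)
    u_worse = r[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = 1.0 - u_worse / (n_pos * n_neg)

    thresholds = np.unique(combined)
    tpr = np.concatenate([[0.0], np.searchsorted(np.sort(pos), thresholds, side="right") / n_pos])
    fpr = np.concatenate([[0.0], np.searchsorted(np.sort(neg), thresholds, side="right") / n_neg])
    points = np.column_stack([fpr, tpr])
    return RocResult(points=points, auc=float(auc), n_pos=n_pos, n_neg=n_neg)


def tpr_at_fraction(
    ranks: RankMapping,
    sets: BenchmarkSets,
    fraction: float,
) -> float:
    """Share of positives ranked within the top ``fraction`` of the universe.

    The cutoff index is ceiling(fraction × N) over the N genes in the rank
    mapping; the threshold is the cutoff-th smallest rank value, and genes
    tied exactly at the threshold count as inside.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if not sets.positives:
        raise ValueError("empty positive set")
    missing = sets.positives - set(ranks)
    if missing:
        raise KeyError(f"positive genes without a rank: {sorted(missing)[:5]}")
    values = np.array(list(ranks.values()), dtype=float)
    cutoff = math.ceil(fraction * len(values))
    threshold = np.partition(values, cutoff - 1)[cutoff - 1]
    pos = np.array([ranks[g] for g in sets.positives], dtype=float)
    return float(np.mean(pos <= threshold))


def sample_negative_genes(
    universe: GeneUniverse,
    n: int,
    excluded: Iterable[str] = (),
    seed: int = 0,
) -> set[str]:
    """Uniform sample of n genes without replacement, avoiding the excluded set.

    Reproducible under ``seed``; raises if fewer than n eligible genes remain.
    """
    excluded = set(excluded)
    eligible = sorted(set(universe.gene_ids) - excluded)
    if len(eligible) < n:
        raise ValueError(
            f"cannot sample {n} genes: only {len(eligible)} eligible after exclusions"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(eligible, size=n, replace=False).tolist())
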