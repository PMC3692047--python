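"""Benchmark protocol: intersection restriction, rank-based ROC/AUC, TPR, sampling."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from generank.core import GeneRecord, GeneUniverse
from generank.evaluate import (
    BenchmarkSets,
    restrict_to_common_universe,
    roc_auc_from_ranks,
    sample_negative_genes,
    tpr_at_fraction,
)


def brute_force_auc(ranks, positives, negatives):
    """All-pairs Mann-Whitney counting with half-credit ties."""
    wins = 0.0
    for p in positives:
        for n in negatives:
            if ranks[p] < ranks[n]:
                wins += 1.0
            elif ranks[p] == ranks[n]:
                wins += 0.5
    return wins / (len(positives) * len(negatives))


class TestBenchmarkSets:
    def test_overlap_rejected_exclusions_removed(self):
        with pytest.raises(ValueError):
            BenchmarkSets(positives={"a"}, negatives={"a", "b"})
        sets = BenchmarkSets(
            positives={"a"}, negatives={"b", "c"}, exclusions={"c"}
        )
        assert sets.negatives == {"b"}


class TestRestriction:
    def test_gene_missing_from_one_ranking_dropped(self):
        r1 = {"a": 1, "b": 2, "c": 3}
        r2 = {"b": 1, "c": 2}
        sets = BenchmarkSets(positives={"a", "b"}, negatives={"c"})
        filtered, restricted = restrict_to_common_universe([r1, r2], sets)
        assert filtered.positives == {"b"}
        assert set(restricted[0]) == {"b", "c"}

    def test_full_overlap_is_identity(self):
        r = {"a": 1, "b": 2, "c": 3}
        sets = BenchmarkSets(positives={"a"}, negatives={"b"})
        filtered, restricted = restrict_to_common_universe([r, dict(r)], sets)
        assert filtered.positives == {"a"} and filtered.negatives == {"b"}
        assert restricted[0] == r

    def test_matches_set_algebra_oracle(self, rng):
        genes = [f"g{i}" for i in range(60)]
        maps = []
        for _ in range(3):
            keep = [g for g in genes if rng.random() < 0.8]
            maps.append({g: float(i + 1) for i, g in enumerate(keep)})
        common = set(maps[0]) & set(maps[1]) & set(maps[2])
        pos = set(genes[:20])
        neg = set(genes[20:40])
        filtered, _ = restrict_to_common_universe(
            maps, BenchmarkSets(positives=pos, negatives=neg)
        )
        assert filtered.positives == pos & common
        assert filtered.negatives == neg & common

    def test_empty_intersection_errors(self):
        sets = BenchmarkSets(positives={"a"}, negatives={"b"})
        with pytest.raises(ValueError):
            restrict_to_common_universe([{"a": 1}, {"b": 1}], sets)


class TestRocAuc:
    def test_perfect_separation(self):
        sets = BenchmarkSets(positives={"p1", "p2"}, negatives={"n1", "n2"})
        roc = roc_auc_from_ranks({"p1": 1, "p2": 2, "n1": 3, "n2": 4}, sets)
        assert roc.auc == 1.0

    def test_interleaved_pairs(self):
        sets = BenchmarkSets(positives={"p1", "p2"}, negatives={"n1", "n2"})
        roc = roc_auc_from_ranks({"p1": 1, "p2": 4, "n1": 2, "n2": 3}, sets)
        assert roc.auc == 0.5

    def test_matches_pair_counting_oracle_and_sklearn(self, rng):
        for _ in range(100):
            n_pos = int(rng.integers(2, 50))
            n_neg = int(rng.integers(2, 50))
            genes = [f"g{i}" for i in range(n_pos + n_neg)]
            # integer ranks induce ties
            ranks = {g: float(rng.integers(1, n_pos + n_neg)) for g in genes}
            pos, neg = set(genes[:n_pos]), set(genes[n_pos:])
            sets = BenchmarkSets(positives=pos, negatives=neg)
            roc = roc_auc_from_ranks(ranks, sets)
            assert roc.auc == pytest.approx(
                brute_force_auc(ranks, pos, neg), abs=1e-12
            )
            labels = [1] * n_pos + [0] * n_neg
            scores = [-ranks[g] for g in genes]
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_reversal_identity_on_tie_free_ranks(self, rng):
        genes = [f"g{i}" for i in range(40)]
        perm = rng.permutation(40) + 1
        ranks = {g: float(r) for g, r in zip(genes, perm)}
        reversed_ranks = {g: 41.0 - r for g, r in ranks.items()}
        sets = BenchmarkSets(positives=set(genes[:15]), negatives=set(genes[15:]))
        a = roc_auc_from_ranks(ranks, sets).auc
        b = roc_auc_from_ranks(reversed_ranks, sets).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_curve_endpoints_and_trapezoid_equals_mann_whitney(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ranks = {g: float(rng.integers(1, 40)) for g in genes}
        sets = BenchmarkSets(positives=set(genes[:25]), negatives=set(genes[25:]))
        roc = roc_auc_from_ranks(ranks, sets)
        assert tuple(roc.points[0]) == (0.0, 0.0)
        assert tuple(roc.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.points[:, 0]) >= 0)
        assert np.all(np.diff(roc.points[:, 1]) >= 0)
        area = np.trapezoid(roc.points[:, 1], roc.points[:, 0])
        assert area == pytest.approx(roc.auc, abs=1e-12)

    def test_auc_invariant_under_monotone_rank_transform(self, rng):
        genes = [f"g{i}" for i in range(30)]
        ranks = {g: float(rng.integers(1, 20)) for g in genes}
        sets = BenchmarkSets(positives=set(genes[:10]), negatives=set(genes[10:]))
        transformed = {g: np.expm1(r / 3.0) for g, r in ranks.items()}
        assert roc_auc_from_ranks(ranks, sets).auc == pytest.approx(
            roc_auc_from_ranks(transformed, sets).auc, abs=1e-12
        )

    def test_random_labels_auc_near_half(self, rng):
        genes = [f"g{i}" for i in range(400)]
        ranks = {g: float(i + 1) for i, g in enumerate(genes)}
        aucs = []
        for _ in range(50):
            labels = rng.permutation(400)
            pos = {genes[i] for i in labels[:200]}
            neg = set(genes) - pos
            sets = BenchmarkSets(positives=pos, negatives=neg)
            aucs.append(roc_auc_from_ranks(ranks, sets).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc_from_ranks({"a": 1}, BenchmarkSets(positives=set(), negatives={"a"}))


class TestTprAtFraction:
    def test_direct_count_at_cutoff(self):
        ranks = {f"g{i}": float(i + 1) for i in range(100)}
        sets = BenchmarkSets(positives={"g0", "g99"}, negatives={"g50"})
        # cutoff = ceil(0.05 * 100) = 5; only g0 inside
        assert tpr_at_fraction(ranks, sets, 0.05) == 0.5

    def test_full_universe_fraction_is_one(self, rng):
        ranks = {f"g{i}": float(rng.integers(1, 50)) for i in range(80)}
        sets = BenchmarkSets(positives={"g0", "g7", "g33"}, negatives={"g50"})
        assert tpr_at_fraction(ranks, sets, 1.0) == 1.0

    def test_matches_brute_force_count(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            ranks = {f"g{i}": float(rng.integers(1, n)) for i in range(n)}
            pos = {f"g{i}" for i in rng.choice(n, size=min(5, n // 2), replace=False)}
            sets = BenchmarkSets(positives=pos, negatives=set())
            frac = float(rng.uniform(0.01, 1.0))
            cutoff = int(np.ceil(frac * n))
            threshold = sorted(ranks.values())[cutoff - 1]
            expected = sum(ranks[p] <= threshold for p in pos) / len(pos)
            assert tpr_at_fraction(ranks, sets, frac) == pytest.approx(expected)

    def test_fraction_bounds(self):
        ranks = {"a": 1.0}
        sets = BenchmarkSets(positives={"a"}, negatives=set())
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                tpr_at_fraction(ranks, sets, bad)


class TestNegativeSampling:
    @pytest.fixture
    def uni(self):
        return GeneUniverse(
            [GeneRecord(f"g{i}", "chr1", 1 + 100 * i, 50 + 100 * i) for i in range(30)]
        )

    def test_exhaustive_sample_returns_all_eligible(self, uni):
        excluded = {f"g{i}" for i in range(10)}
        sample = sample_negative_genes(uni, 20, excluded, seed=3)
        assert sample == set(uni.gene_ids) - excluded

    def test_reproducible_under_seed(self, uni):
        a = sample_negative_genes(uni, 10, set(), seed=42)
        b = sample_negative_genes(uni, 10, set(), seed=42)
        assert a == b

    def test_excluded_never_sampled_across_seeds(self, uni):
        excluded = {"g0", "g5", "g10"}
        for seed in range(100):
            sample = sample_negative_genes(uni, 15, excluded, seed=seed)
            assert not (sample & excluded)

    def test_insufficient_eligible_errors(self, uni):
        with pytest.raises(ValueError):
            sample_negative_genes(uni, 25, {f"g{i}" for i in range(10)}, seed=1)
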