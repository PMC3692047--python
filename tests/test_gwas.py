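"""GWAS layer: SNP-gene mapping, best-SNP assignment, Li-Ji correction, adjustment."""

import numpy as np
import pytest
import scipy.linalg

from generank.core import GeneRecord, GeneUniverse
from generank.gwas import (
    LdPanel,
    SnpRecord,
    adjust_gene_pvalue,
    best_snp_per_gene,
    effective_tests_li_ji,
    estimate_ld_correlation,
    gwas_layer_scores,
    map_snps_to_genes,
)


def li_ji_oracle(corr):
    """Independent route: general (non-symmetric) eigensolver + direct f summation."""
    lam = np.abs(scipy.linalg.eigvals(np.asarray(corr, dtype=float)))
    return float(sum((1.0 if x >= 1.0 else 0.0) + (x - np.floor(x)) for x in lam))


def random_correlation(rng, m):
    a = rng.normal(size=(m, m + 3))
    cov = a @ a.T
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


class TestSnpGeneMapping:
    def test_interior_and_boundary_semantics(self, universe):
        snps = [
            SnpRecord("rs1", "chr1", 500, 0.5),    # inside G1 body
            SnpRecord("rs2", "chr1", 1050, 0.5),   # 50 bp past G1 end
            SnpRecord("rs3", "chr1", 1051, 0.5),   # 51 bp past G1 end
        ]
        mapped, n_unmapped = map_snps_to_genes(snps, universe, window_bp=50)
        assert "rs1" in mapped["G1"] and "rs2" in mapped["G1"]
        assert "rs3" not in mapped.get("G1", [])

    def test_unknown_chromosome_counts_unmapped(self, universe):
        mapped, n_unmapped = map_snps_to_genes(
            [SnpRecord("rs1", "chr99", 500, 0.5)], universe, window_bp=0
        )
        assert mapped == {} and n_unmapped == 1

    def test_snp_maps_to_all_overlapping_windows(self):
        genes = [
            GeneRecord(f"G{i}", "chr1", start, start + 100)
            for i, start in enumerate([1000, 1100, 1200])
        ]
        uni = GeneUniverse(genes)
        mapped, _ = map_snps_to_genes(
            [SnpRecord("rs1", "chr1", 1150, 0.1)], uni, window_bp=200
        )
        assert sorted(mapped) == ["G0", "G1", "G2"]

    def test_matches_brute_force_interval_scan(self, rng):
        genes = [
            GeneRecord(f"G{i}", f"chr{1 + i % 2}", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(1, 100_000, 60), rng.integers(100, 5000, 60))
            )
        ]
        uni = GeneUniverse(genes)
        snps = [
            SnpRecord(f"rs{j}", f"chr{1 + j % 3}", int(p), 0.5)
            for j, p in enumerate(rng.integers(1, 110_000, 300))
        ]
        window = 1000
        mapped, n_unmapped = map_snps_to_genes(snps, uni, window)
        expected: dict[str, list[str]] = {}
        lost = 0
        for snp in snps:
            hit = False
            for g in genes:
                if g.chrom == snp.chrom and g.start - window <= snp.pos <= g.end + window:
                    expected.setdefault(g.gene_id, []).append(snp.snp_id)
                    hit = True
            lost += not hit
        assert n_unmapped == lost
        assert {g: sorted(v) for g, v in mapped.items()} == {
            g: sorted(v) for g, v in expected.items()
        }

    def test_input_order_invariance(self, universe, rng):
        snps = [
            SnpRecord(f"rs{j}", "chr1", int(p), 0.5)
            for j, p in enumerate(rng.integers(1, 10_000, 100))
        ]
        a, _ = map_snps_to_genes(snps, universe, 500)
        b, _ = map_snps_to_genes(list(reversed(snps)), universe, 500)
        assert a == b


class TestBestSnp:
    def test_minimum_pvalue_wins(self):
        snps = {
            "rs1": SnpRecord("rs1", "chr1", 1, 0.5),
            "rs2": SnpRecord("rs2", "chr1", 2, 0.01),
            "rs3": SnpRecord("rs3", "chr1", 3, 0.2),
        }
        best = best_snp_per_gene({"G1": ["rs1", "rs2", "rs3"]}, snps)
        assert best["G1"] == ("rs2", 0.01)

    def test_pvalue_tie_broken_lexicographically(self):
        snps = {
            "rs2": SnpRecord("rs2", "chr1", 1, 0.01),
            "rs10": SnpRecord("rs10", "chr1", 2, 0.01),
        }
        best = best_snp_per_gene({"G1": ["rs2", "rs10"]}, snps)
        assert best["G1"][0] == "rs10"  # "rs10" < "rs2" lexicographically

    def test_matches_brute_force_minimum(self, rng):
        pvals = rng.random(1000)
        snps = {
            f"rs{i}": SnpRecord(f"rs{i}", "chr1", i + 1, float(p))
            for i, p in enumerate(pvals)
        }
        best = best_snp_per_gene({"G1": list(snps)}, snps)
        assert best["G1"][1] == pytest.approx(min(pvals), abs=0)


class TestLiJi:
    def test_identity_gives_m(self):
        for m in (1, 2, 5, 8):
            assert effective_tests_li_ji(np.eye(m)) == float(m)

    def test_all_ones_gives_one(self):
        for m in (2, 4, 7):
            assert effective_tests_li_ji(np.ones((m, m))) == 1.0

    def test_two_by_two_closed_form(self):
        # eigenvalues 1 ± r: f(1.5) = 1.5, f(0.5) = 0.5
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert effective_tests_li_ji(corr) == pytest.approx(2.0, abs=1e-12)

    def test_agrees_with_independent_eigendecomposition(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 11))
            corr = random_correlation(rng, m)
            ours = effective_tests_li_ji(corr)
            oracle = li_ji_oracle(corr)
            assert ours == pytest.approx(oracle, rel=1e-9)
            assert 1.0 <= ours <= m + 1e-12

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            effective_tests_li_ji(np.array([[1.0, 0.5], [0.1, 1.0]]))  # asymmetric
        with pytest.raises(ValueError):
            effective_tests_li_ji(np.array([[2.0, 0.0], [0.0, 1.0]]))  # diagonal != 1

    def test_single_snp_is_one(self):
        assert effective_tests_li_ji(np.array([[1.0]])) == 1.0


class TestLdEstimation:
    def test_self_and_duplicate_column_correlation(self, rng):
        col = rng.binomial(2, 0.5, 50).astype(float)
        panel = LdPanel(["a", "b"], np.column_stack([col, col]))
        corr = estimate_ld_correlation(panel, ["a", "b"])
        assert corr[0, 0] == 1.0
        assert corr[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self, rng):
        # generative correlation 0.8 via shared template copying
        n = 2000
        template = rng.binomial(2, 0.5, n).astype(float)
        c = np.sqrt(0.8)
        x = np.where(rng.random(n) < c, template, rng.binomial(2, 0.5, n))
        y = np.where(rng.random(n) < c, template, rng.binomial(2, 0.5, n))
        panel = LdPanel(["x", "y"], np.column_stack([x, y]))
        est = estimate_ld_correlation(panel, ["x", "y"])[0, 1]
        sx, sy = x - x.mean(), y - y.mean()
        textbook = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert est == pytest.approx(textbook, abs=1e-12)
        assert est == pytest.approx(0.8, abs=0.08)  # sampling error at n=2000

    def test_monomorphic_snp_defined_as_zero(self):
        panel = LdPanel(
            ["mono", "poly"],
            np.column_stack([np.ones(10), np.arange(10) % 3]).astype(float),
        )
        corr = estimate_ld_correlation(panel, ["mono", "poly"])
        assert corr[0, 1] == 0.0 and corr[0, 0] == 1.0

    def test_missing_snp_named_in_error(self, rng):
        panel = LdPanel(["a"], rng.binomial(2, 0.5, (10, 1)).astype(float))
        with pytest.raises(KeyError, match="ghost"):
            estimate_ld_correlation(panel, ["a", "ghost"])

    def test_pairwise_complete_with_missing_values(self, rng):
        x = rng.binomial(2, 0.5, 30).astype(float)
        y = x.copy()
        x[:3] = np.nan
        panel = LdPanel(["x", "y"], np.column_stack([x, y]))
        corr = estimate_ld_correlation(panel, ["x", "y"])
        assert corr[0, 1] == pytest.approx(1.0)


class TestAdjustment:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.01, 1.0, 0.01), (0.01, 2.0, 0.019900), (0.0, 7.3, 0.0), (1.0, 4.0, 1.0)],
    )
    def test_sidak_values(self, p, m, expected):
        assert adjust_gene_pvalue(p, m) == pytest.approx(expected, abs=1e-9)

    def test_bonferroni_option(self):
        assert adjust_gene_pvalue(0.01, 3.0, method="bonferroni") == pytest.approx(0.03)
        assert adjust_gene_pvalue(0.5, 4.0, method="bonferroni") == 1.0

    def test_monotone_and_bounded(self, rng):
        for _ in range(50):
            p = float(rng.random())
            m1, m2 = sorted(rng.uniform(1, 20, 2))
            a1, a2 = adjust_gene_pvalue(p, m1), adjust_gene_pvalue(p, m2)
            assert p <= a1 <= a2 <= 1.0


class TestGwasLayer:
    def test_single_snp_no_panel(self, universe):
        result = gwas_layer_scores(
            [SnpRecord("rs1", "chr1", 500, 0.05)], universe, window_bp=0
        )
        (diag,) = result.assignments
        assert diag.m_eff == 1.0
        assert result.layer.scores == {"G1": 0.05}
        assert result.layer.direction == "ascending"

    def test_perfect_ld_with_and_without_panel(self, universe):
        snps = [
            SnpRecord("rs1", "chr1", 300, 0.05),
            SnpRecord("rs2", "chr1", 400, 0.30),
            SnpRecord("rs3", "chr1", 500, 0.70),
        ]
        rng = np.random.default_rng(7)
        col = rng.binomial(2, 0.5, 40).astype(float)
        panel = LdPanel(["rs1", "rs2", "rs3"], np.column_stack([col, col, col]))
        with_panel = gwas_layer_scores(snps, universe, window_bp=0, panel=panel)
        without = gwas_layer_scores(snps, universe, window_bp=0)
        assert with_panel.assignments[0].m_eff == pytest.approx(1.0)
        assert with_panel.layer.scores["G1"] == pytest.approx(0.05)
        assert without.assignments[0].m_eff == 3.0
        assert without.layer.scores["G1"] == pytest.approx(1 - 0.95**3)

    def test_no_panel_fallback_upper_bounds_panel_adjustment(self, rng):
        # conservatism: panel-derived m_eff <= n_snps implies smaller p_adj
        genes = [GeneRecord(f"G{i}", "chr1", 1 + 10_000 * i, 9_000 + 10_000 * i)
                 for i in range(10)]
        uni = GeneUniverse(genes)
        snps = [
            SnpRecord(f"rs{j:03d}", "chr1", int(p), float(rng.random()))
            for j, p in enumerate(rng.integers(1, 100_000, 200))
        ]
        n = len(snps)
        template = rng.binomial(2, 0.5, (60, n // 4 + 1)).astype(float)
        blocks = np.repeat(np.arange(n // 4 + 1), 4)[:n]
        geno = template[:, blocks].copy()
        flip = rng.random(geno.shape) < 0.3
        geno[flip] = rng.binomial(2, 0.5, flip.sum())
        panel = LdPanel([s.snp_id for s in snps], geno)
        with_panel = gwas_layer_scores(snps, uni, window_bp=500, panel=panel)
        without = gwas_layer_scores(snps, uni, window_bp=500)
        fallback = {d.gene_id: d for d in without.assignments}
        for diag in with_panel.assignments:
            other = fallback[diag.gene_id]
            assert 1.0 <= diag.m_eff <= diag.n_snps + 1e-9
            assert diag.p_adj <= other.p_adj + 1e-12
            assert diag.p_adj >= diag.best_p - 1e-12

    def test_snp_order_permutation_invariance(self, universe, rng):
        snps = [
            SnpRecord(f"rs{j}", "chr1", int(p), float(rng.random()))
            for j, p in enumerate(rng.integers(1, 10_000, 80))
        ]
        a = gwas_layer_scores(snps, universe, window_bp=2000)
        perm = [snps[i] for i in rng.permutation(len(snps))]
        b = gwas_layer_scores(perm, universe, window_bp=2000)
        assert a.layer.scores == b.layer.scores
        assert [d.__dict__ for d in a.assignments] == [d.__dict__ for d in b.assignments]

    def test_zero_mapped_snps_is_error(self, universe):
        with pytest.raises(ValueError):
            gwas_layer_scores(
                [SnpRecord("rs1", "chrZ", 5, 0.1)], universe, window_bp=0
            )
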