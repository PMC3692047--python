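"""GWAS-based gene scoring.

Three-step procedure: (i) map SNPs to genes by physical proximity,
(ii) assign each gene the P-value of its best-associated SNP, and
(iii) adjust the gene P-value by the effective number of independent SNPs
mapped to the gene, computed with the Li & Ji eigenvalue rule from a
linkage-disequilibrium (LD) correlation matrix. Without an LD reference
panel the effective test count falls back to the raw SNP count, the most
conservative choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import EvidenceLayer, GeneUniverse

DEFAULT_WINDOW_BP = 50_000


@dataclass(frozen=True)
class SnpRecord:
    """One SNP association result: id, position, P-value."""

    snp_id: str
    chrom: str
    pos: int
    pvalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"SNP {self.snp_id}: P-value {self.pvalue} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position {self.pos} < 1")


@dataclass
class LdPanel:
    """Genotype reference panel: sample × SNP dosage matrix {0,1,2}, NaN = missing."""

    snp_ids: list[str]
    genotypes: np.ndarray  # shape (n_samples, n_snps), float with NaN for missing
    _col: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D sample × SNP matrix")
        if self.genotypes.shape[0] < 2:
            raise ValueError("LD panel needs at least 2 samples")
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValueError(
                f"genotype matrix has {self.genotypes.shape[1]} columns "
                f"but {len(self.snp_ids)} SNP ids"
            )
        self._col = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._col

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self._col[snp_id]]


@dataclass
class GeneSnpAssignment:
    """Per-gene GWAS diagnostics: mapped SNPs, best SNP, effective tests, adjusted P."""

    gene_id: str
    snp_ids: list[str]
    n_snps: int
    best_snp: str
    best_p: float
    m_eff: float
    p_adj: float


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    universe: GeneUniverse,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> tuple[dict[str, list[str]], int]:
    """Map each SNP to every gene whose window contains it.

    SNP ``s`` maps to gene ``g`` iff the chromosomes match and
    ``g.start - window_bp <= s.pos <= g.end + window_bp`` (1-based, inclusive
    on both sides). A SNP may map to several overlapping genes. Returns the
    per-gene SNP lists (sorted by position then id, so the result is
    independent of input order) and the count of unmapped SNPs.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be non-negative, got {window_bp}")
    trees: dict[str, IntervalTree] = {}
    for gene in universe:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        # intervaltree is half-open; +1 makes the inclusive end queryable
        tree.addi(gene.start - window_bp, gene.end + window_bp + 1, gene.gene_id)
    hits: dict[str, list[tuple[int, str]]] = {}
    n_unmapped = 0
    for snp in snps:
        tree = trees.get(snp.chrom)
        matches = tree[snp.pos] if tree is not None else ()
        if not matches:
            n_unmapped += 1
            continue
        for iv in matches:
            hits.setdefault(iv.data, []).append((snp.pos, snp.snp_id))
    assignment = {
        gene_id: [snp_id for _, snp_id in sorted(pairs)]
        for gene_id, pairs in hits.items()
    }
    return assignment, n_unmapped


def best_snp_per_gene(
    assignment: dict[str, list[str]],
    snps: dict[str, SnpRecord],
) -> dict[str, tuple[str, float]]:
    """Pick each gene's best-associated SNP (minimum P-value).

    Ties on the P-value are broken by the lexicographically smallest SNP id so
    the result is deterministic.
    """
    out: dict[str, tuple[str, float]] = {}
    for gene_id, snp_ids in assignment.items():
        if not snp_ids:
            raise ValueError(f"gene {gene_id} has no mapped SNPs")
        best = min(snp_ids, key=lambda s: (snps[s].pvalue, s))
        out[gene_id] = (best, snps[best].pvalue)
    return out


def effective_tests_li_ji(corr: np.ndarray) -> float:
    """Effective number of independent tests from a SNP correlation matrix.

    The Li & Ji rule: M_eff = Σ_i f(|λ_i|) over the eigenvalues λ_i of the
    correlation matrix, with f(x) = 1{x ≥ 1} + (x − ⌊x⌋). Identity gives M
    (independent SNPs), the all-ones matrix gives 1 (perfect LD). Eigenvalue
    magnitudes are rounded to 10 decimals before f(·): f is discontinuous at
    integers and exact structured matrices must land on the closed form
    despite eigensolver round-off.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    if np.any(np.abs(corr) > 1.0 + 1e-8):
        raise ValueError("correlation entries must lie in [-1, 1]")
    if corr.shape[0] == 1:
        return 1.0
    lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 10)
    m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    # rounding dust can push the sum marginally past the [1, M] bounds
    return float(min(max(m_eff, 1.0), corr.shape[0]))


def estimate_ld_correlation(panel: LdPanel, snp_subset: Sequence[str]) -> np.ndarray:
    """Pairwise-complete Pearson correlation of dosages for a SNP subset.

    Monomorphic SNPs (zero variance) and pairs with fewer than two complete
    observations get correlation 0 off-diagonal and 1 on the diagonal.
    """
    missing = [s for s in snp_subset if s not in panel]
    if missing:
        raise KeyError(f"SNP {missing[0]!r} absent from the LD panel")
    cols = np.column_stack([panel.column(s) for s in snp_subset])
    if np.isnan(cols).any():
        corr = pd.DataFrame(cols).corr(min_periods=2).to_numpy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(cols, rowvar=False)
        corr = np.atleast_2d(corr)
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def adjust_gene_pvalue(best_p: float, m_eff: float, method: str = "sidak") -> float:
    """Adjust a gene's best-SNP P-value for its effective number of tests.

    ``sidak`` (default): p_adj = 1 − (1 − p)^m_eff, bounded in [p, 1] and
    monotone in both arguments. ``bonferroni``: min(1, p · m_eff).
    """
    if not 0.0 <= best_p <= 1.0:
        raise ValueError(f"best_p {best_p} outside [0, 1]")
    if m_eff < 1.0:
        raise ValueError(f"m_eff {m_eff} < 1")
    if method == "sidak":
        if best_p >= 1.0:
            return 1.0
        return float(-math.expm1(m_eff * math.log1p(-best_p)))
    if method == "bonferroni":
        return min(1.0, best_p * m_eff)
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass
class GwasLayerResult:
    """GWAS evidence layer plus per-gene diagnostics."""

    layer: EvidenceLayer
    assignments: list[GeneSnpAssignment]
    n_unmapped_snps: int


def _gene_m_eff(snp_ids: list[str], panel: LdPanel | None) -> float:
    """Effective test count for one gene's SNPs.

    No panel: fall back to the raw SNP count (most conservative). With a
    panel, SNPs absent from it are treated as independent and add 1 each.
    """
    if panel is None:
        return float(len(snp_ids))
    covered = [s for s in snp_ids if s in panel]
    uncovered = len(snp_ids) - len(covered)
    m_eff = float(uncovered)
    if covered:
        m_eff += effective_tests_li_ji(estimate_ld_correlation(panel, covered))
    return m_eff


def gwas_layer_scores(
    snps: Iterable[SnpRecord],
    universe: GeneUniverse,
    window_bp: int = DEFAULT_WINDOW_BP,
    panel: LdPanel | None = None,
    adjustment: str = "sidak",
) -> GwasLayerResult:
    """Score genes from GWAS summary statistics (ascending layer of adjusted P-values)."""
    snp_list = list(snps)
    snp_index = {s.snp_id: s for s in snp_list}
    if len(snp_index) != len(snp_list):
        raise ValueError("duplicate SNP ids in GWAS input")
    assignment, n_unmapped = map_snps_to_genes(snp_list, universe, window_bp)
    if not assignment:
        raise ValueError("no SNP maps to any gene; cannot build the GWAS layer")
    best = best_snp_per_gene(assignment, snp_index)
    scores: dict[str, float] = {}
    diagnostics: list[GeneSnpAssignment] = []
    for gene_id in sorted(assignment):
        snp_ids = assignment[gene_id]
        best_snp, best_p = best[gene_id]
        m_eff = _gene_m_eff(snp_ids, panel)
        p_adj = adjust_gene_pvalue(best_p, m_eff, method=adjustment)
        scores[gene_id] = p_adj
        diagnostics.append(
            GeneSnpAssignment(
                gene_id=gene_id,
                snp_ids=snp_ids,
                n_snps=len(snp_ids),
                best_snp=best_snp,
                best_p=best_p,
                m_eff=m_eff,
                p_adj=p_adj,
            )
        )
    layer = EvidenceLayer(name="gwas", scores=scores, direction="ascending")
    return GwasLayerResult(layer=layer, assignments=diagnostics, n_unmapped_snps=n_unmapped)
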