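"""Seeded synthetic data for every evidence layer.

A :class:`SyntheticScenario` plants a small set of causal genes and emulates
the study inputs around them: GWAS summary statistics with association signal
concentrated in causal genes and blockwise linkage disequilibrium, a
confidence-weighted interaction network with causal genes wired to a seed set
of known phenotype genes, a document–term corpus in which causal genes are
co-mentioned with a phenotype term, chromosomal regions covering causal loci,
and a binary custom gene list with stated recall and precision. The null
construction (no planted signal anywhere) is available via
:meth:`SyntheticScenario.null` for calibration checks.

Everything is deterministic under the scenario seed; each component draws
from its own seeded stream so layers can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import networkx as nx
import scipy.sparse as sp

from .core import GeneRecord, GeneUniverse
from .gwas import LdPanel, SnpRecord
from .network import InteractionNetwork
from .regions import CustomLayerSpec, GenomicRegion
from .text import SparseCorpus

# per-component offsets for derived random streams
_STREAM_CAUSAL = 1
_STREAM_UNIVERSE = 2
_STREAM_GWAS = 3
_STREAM_NETWORK = 4
_STREAM_CORPUS = 5
_STREAM_CUSTOM = 6
_STREAM_REGIONS = 7


@dataclass(frozen=True)
class SyntheticScenario:
    """Knobs of the planted-causal-gene benchmark; defaults are the study conditions."""

    seed: int = 0
    # genome / universe
    n_genes: int = 1000
    n_chromosomes: int = 5
    chrom_span_bp: int = 20_000_000
    gene_length_range: tuple[int, int] = (20_000, 60_000)
    n_causal: int = 20
    # GWAS layer
    n_snps: int = 10_000
    causal_pvalue_beta_a: float = 0.15  # Beta(a, 1) for SNPs in causal genes; 1.0 = null
    ld_block_size: int = 5
    ld_block_r: float = 0.8  # within-block dosage correlation
    n_panel_samples: int = 100
    # network layer
    n_seeds: int = 30
    background_edge_prob: float = 0.004
    background_conf_range: tuple[float, float] = (0.1, 1.0)
    causal_seed_edge_prob: float = 0.25  # set equal to background for a null network
    causal_seed_conf_range: tuple[float, float] = (0.6, 1.0)
    # text layer
    n_docs: int = 400
    vocab_size: int = 300
    n_signal_tokens: int = 40
    n_term_docs: int = 80
    tokens_per_doc: int = 12
    term_doc_signal_frac: float = 0.7
    mean_docs_per_gene: float = 3.0
    causal_term_doc_prob: float = 0.08  # 0.0 = null text layer
    phenotype_term: str = "phenotype_term"
    # custom layer
    custom_recall: float = 0.9
    custom_precision: float = 0.9
    custom_from_causal: bool = True
    # region layer
    region_recall: float = 0.8
    region_pad_bp: int = 10_000
    n_decoy_regions: int = 10
    decoy_span_bp: int = 100_000
    regions_from_causal: bool = True

    def __post_init__(self) -> None:
        if self.n_causal >= self.n_genes:
            raise ValueError("n_causal must be smaller than n_genes")
        for name in (
            "causal_seed_edge_prob", "background_edge_prob", "ld_block_r",
            "causal_term_doc_prob", "custom_recall", "custom_precision",
            "region_recall", "term_doc_signal_frac",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def null(self) -> "SyntheticScenario":
        """Same scenario with every planted signal removed."""
        return replace(
            self,
            causal_pvalue_beta_a=1.0,
            causal_seed_edge_prob=self.background_edge_prob,
            causal_seed_conf_range=self.background_conf_range,
            causal_term_doc_prob=0.0,
            custom_from_causal=False,
            regions_from_causal=False,
        )


def simulate_universe(scenario: SyntheticScenario) -> GeneUniverse:
    """Non-overlapping genes with coordinates and all three synonym nomenclatures."""
    rng = scenario.rng(_STREAM_UNIVERSE)
    per_chrom = np.full(scenario.n_chromosomes, scenario.n_genes // scenario.n_chromosomes)
    per_chrom[: scenario.n_genes % scenario.n_chromosomes] += 1
    lo, hi = scenario.gene_length_range
    genes: list[GeneRecord] = []
    idx = 0
    for c, n_on_chrom in enumerate(per_chrom, start=1):
        lengths = rng.integers(lo, hi + 1, size=n_on_chrom)
        free = scenario.chrom_span_bp - int(lengths.sum()) - n_on_chrom
        if free < 0:
            raise ValueError(
                f"chromosome span {scenario.chrom_span_bp} too small for "
                f"{n_on_chrom} genes of length up to {hi}"
            )
        gaps = rng.dirichlet(np.ones(n_on_chrom + 1)) * free
        pos = 1
        for i in range(n_on_chrom):
            pos += int(gaps[i]) + 1
            start = pos
            end = start + int(lengths[i]) - 1
            pos = end
            genes.append(
                GeneRecord(
                    gene_id=f"G{idx:04d}",
                    chrom=f"chr{c}",
                    start=start,
                    end=end,
                    synonyms={
                        "ensembl": f"ENSG{idx:011d}",
                        "symbol": f"GENE{idx}",
                        "entrez": str(100000 + idx),
                    },
                )
            )
            idx += 1
    return GeneUniverse(genes)


def select_causal_genes(scenario: SyntheticScenario, universe: GeneUniverse) -> list[str]:
    """The planted causal genes; deterministic under the scenario seed."""
    rng = scenario.rng(_STREAM_CAUSAL)
    return sorted(
        rng.choice(universe.gene_ids, size=scenario.n_causal, replace=False).tolist()
    )


def simulate_gwas(
    scenario: SyntheticScenario, universe: GeneUniverse
) -> tuple[list[SnpRecord], LdPanel]:
    """GWAS summary statistics plus a genotype reference panel.

    SNPs are placed uniformly per chromosome; null SNPs draw P ~ Uniform(0,1)
    and SNPs inside a causal gene body draw P ~ Beta(a, 1) with a < 1 (the
    smaller a, the stronger the planted association). Panel genotypes carry
    blockwise LD: within a block each SNP copies a shared template genotype
    with probability sqrt(r), giving pairwise dosage correlation r.
    """
    rng = scenario.rng(_STREAM_GWAS)
    causal = set(select_causal_genes(scenario, universe))
    causal_intervals: dict[str, list[tuple[int, int]]] = {}
    for g in universe:
        if g.gene_id in causal:
            causal_intervals.setdefault(g.chrom, []).append((g.start, g.end))

    per_chrom = np.full(scenario.n_chromosomes, scenario.n_snps // scenario.n_chromosomes)
    per_chrom[: scenario.n_snps % scenario.n_chromosomes] += 1
    snps: list[SnpRecord] = []
    idx = 0
    for c, n_on_chrom in enumerate(per_chrom, start=1):
        chrom = f"chr{c}"
        positions = np.sort(rng.integers(1, scenario.chrom_span_bp + 1, size=n_on_chrom))
        intervals = causal_intervals.get(chrom, [])
        for pos in positions:
            in_causal = any(s <= pos <= e for s, e in intervals)
            if in_causal and scenario.causal_pvalue_beta_a < 1.0:
                p = float(rng.beta(scenario.causal_pvalue_beta_a, 1.0))
            else:
                p = float(rng.uniform())
            snps.append(SnpRecord(snp_id=f"rs{idx:06d}", chrom=chrom, pos=int(pos), pvalue=p))
            idx += 1

    # blockwise LD: consecutive SNPs per chromosome share a template genotype
    n_total = len(snps)
    n_samples = scenario.n_panel_samples
    copy_prob = float(np.sqrt(scenario.ld_block_r))
    genotypes = rng.binomial(2, 0.5, size=(n_samples, n_total)).astype(float)
    block_ids = np.empty(n_total, dtype=int)
    offset = 0
    block = 0
    for n_on_chrom in per_chrom:
        for j in range(n_on_chrom):
            if j % scenario.ld_block_size == 0:
                block += 1
            block_ids[offset + j] = block
        offset += n_on_chrom
    n_blocks = block + 1
    templates = rng.binomial(2, 0.5, size=(n_samples, n_blocks)).astype(float)
    copy_mask = rng.uniform(size=(n_samples, n_total)) < copy_prob
    genotypes[copy_mask] = templates[:, block_ids][copy_mask]
    panel = LdPanel(snp_ids=[s.snp_id for s in snps], genotypes=genotypes)
    return snps, panel


def simulate_network(
    scenario: SyntheticScenario, universe: GeneUniverse
) -> tuple[InteractionNetwork, list[str]]:
    """Background random interactome plus a denser causal-gene/seed module.

    Returns the network and the seed gene list (known phenotype genes, drawn
    from the non-causal background so positives and seeds stay disjoint).
    """
    rng = scenario.rng(_STREAM_NETWORK)
    gene_ids = universe.gene_ids
    causal = set(select_causal_genes(scenario, universe))
    non_causal = [g for g in gene_ids if g not in causal]
    seeds = sorted(rng.choice(non_causal, size=scenario.n_seeds, replace=False).tolist())

    graph = nx.fast_gnp_random_graph(
        len(gene_ids),
        scenario.background_edge_prob,
        seed=int(rng.integers(2**31 - 1)),
    )
    # causal-seed pairs are governed exclusively by their own edge process;
    # background draws there would double their edge chance in a null scenario
    index = {g: i for i, g in enumerate(gene_ids)}
    causal_seed_pairs = {
        frozenset((index[g], index[s])) for g in causal for s in seeds
    }
    lo, hi = scenario.background_conf_range
    edges: list[tuple[str, str, float]] = []
    for i, j in graph.edges():
        if frozenset((i, j)) in causal_seed_pairs:
            continue
        edges.append((gene_ids[i], gene_ids[j], float(rng.uniform(lo, hi))))
    clo, chi = scenario.causal_seed_conf_range
    for gene in sorted(causal):
        for seed_gene in seeds:
            if rng.uniform() < scenario.causal_seed_edge_prob:
                edges.append((gene, seed_gene, float(rng.uniform(clo, chi))))
    return InteractionNetwork(edges), seeds


def simulate_corpus(scenario: SyntheticScenario, universe: GeneUniverse) -> SparseCorpus:
    """Document–term corpus with causal genes co-mentioned with the phenotype term.

    The first ``n_term_docs`` documents are annotated to the phenotype term
    and draw most tokens from a dedicated signal vocabulary; the remainder
    draw uniformly. Every gene is annotated to a Poisson number of background
    documents; causal genes additionally join phenotype-term documents with
    probability ``causal_term_doc_prob``.
    """
    rng = scenario.rng(_STREAM_CORPUS)
    n_docs, vocab_size = scenario.n_docs, scenario.vocab_size
    doc_ids = [f"d{i:04d}" for i in range(n_docs)]
    vocab = [f"tok{i:03d}" for i in range(vocab_size)]
    signal_tokens = np.arange(scenario.n_signal_tokens)

    rows, cols, data = [], [], []
    for d in range(n_docs):
        if d < scenario.n_term_docs:
            n_signal = rng.binomial(scenario.tokens_per_doc, scenario.term_doc_signal_frac)
            toks = np.concatenate([
                rng.choice(signal_tokens, size=n_signal),
                rng.integers(0, vocab_size, size=scenario.tokens_per_doc - n_signal),
            ])
        else:
            toks = rng.integers(0, vocab_size, size=scenario.tokens_per_doc)
        uniq, counts = np.unique(toks, return_counts=True)
        rows.extend([d] * len(uniq))
        cols.extend(uniq.tolist())
        data.extend(counts.tolist())
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(n_docs, vocab_size), dtype=float
    )

    causal = set(select_causal_genes(scenario, universe))
    background_docs = np.arange(scenario.n_term_docs, n_docs)
    doc_genes: dict[str, list[str]] = {d: [] for d in doc_ids}
    for gene in universe.gene_ids:
        k = rng.poisson(scenario.mean_docs_per_gene)
        if k > 0:
            for d in rng.choice(background_docs, size=min(k, len(background_docs)), replace=False):
                doc_genes[doc_ids[d]].append(gene)
        if gene in causal and scenario.causal_term_doc_prob > 0.0:
            joins = rng.uniform(size=scenario.n_term_docs) < scenario.causal_term_doc_prob
            for d in np.flatnonzero(joins):
                doc_genes[doc_ids[d]].append(gene)
    doc_terms = {doc_ids[d]: [scenario.phenotype_term] for d in range(scenario.n_term_docs)}
    doc_genes = {d: genes for d, genes in doc_genes.items() if genes}
    return SparseCorpus(
        doc_ids=doc_ids, vocab=vocab, counts=counts,
        doc_genes=doc_genes, doc_terms=doc_terms,
    )


def simulate_custom(scenario: SyntheticScenario, universe: GeneUniverse) -> CustomLayerSpec:
    """Binary custom layer emulating a knockout-phenotype gene list.

    With ``custom_from_causal`` the list covers causal genes at the stated
    recall and is diluted to the stated precision with non-causal genes;
    otherwise (null) the same number of genes is drawn at random.
    """
    rng = scenario.rng(_STREAM_CUSTOM)
    causal = select_causal_genes(scenario, universe)
    n_true = int(round(scenario.custom_recall * len(causal)))
    n_false = int(round(n_true * (1.0 - scenario.custom_precision) / scenario.custom_precision))
    if scenario.custom_from_causal:
        listed = rng.choice(causal, size=n_true, replace=False).tolist()
        non_causal = [g for g in universe.gene_ids if g not in set(causal)]
        listed += rng.choice(non_causal, size=n_false, replace=False).tolist()
    else:
        listed = rng.choice(universe.gene_ids, size=n_true + n_false, replace=False).tolist()
    table = {universe.get(g).synonyms.get("symbol", g): None for g in sorted(listed)}
    return CustomLayerSpec(
        name="knockout_list", table=table, nomenclature="auto",
        direction=None, binary_mode=True,
    )


def simulate_regions(scenario: SyntheticScenario, universe: GeneUniverse) -> list[GenomicRegion]:
    """Chromosomal regions covering causal loci plus random decoy regions."""
    rng = scenario.rng(_STREAM_REGIONS)
    regions: list[GenomicRegion] = []
    if scenario.regions_from_causal:
        for gene_id in select_causal_genes(scenario, universe):
            if rng.uniform() < scenario.region_recall:
                g = universe.get(gene_id)
                regions.append(
                    GenomicRegion(
                        chrom=g.chrom,
                        start=max(1, g.start - scenario.region_pad_bp),
                        end=g.end + scenario.region_pad_bp,
                    )
                )
    n_random = scenario.n_decoy_regions if scenario.regions_from_causal else (
        scenario.n_decoy_regions + int(round(scenario.region_recall * scenario.n_causal))
    )
    for _ in range(n_random):
        chrom = f"chr{int(rng.integers(1, scenario.n_chromosomes + 1))}"
        start = int(rng.integers(1, max(2, scenario.chrom_span_bp - scenario.decoy_span_bp)))
        regions.append(
            GenomicRegion(chrom=chrom, start=start, end=start + scenario.decoy_span_bp - 1)
        )
    return regions
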