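"""Meta-rank integration: collapse per-layer normalized ranks into one ranking.

The meta-score of a gene is the geometric mean of its normalized ranks over
the layers that scored it (a rank-product variant): scale-free, invariant to
monotone transformations of any layer's raw scores, and tolerant of layers
that score only part of the universe. A ``worst_rank`` policy substitutes the
worst possible normalized rank (1.0) for missing layers instead, for
sensitivity analysis. Genes likely associated with the trait, given the
evidence layers, end up at the top of the meta-rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import GeneUniverse, RankVector
from .gwas import GeneSnpAssignment

MissingPolicy = Literal["geometric_mean_available", "worst_rank"]

GWAS_DIAG_COLUMNS = ("n_snps", "best_snp", "best_p", "m_eff")


@dataclass
class MetaRankTable:
    """Integrated ranking with per-layer normalized ranks and GWAS diagnostics.

    ``table`` has one row per ranked gene, sorted by meta_rank; genes scored
    by no layer are excluded from the ranking and listed in ``unscored``.
    """

    table: pd.DataFrame
    layer_names: list[str]
    unscored: list[str] = field(default_factory=list)

    def rank_mapping(self) -> dict[str, int]:
        """gene_id → meta_rank (smaller = better)."""
        return dict(zip(self.table["gene_id"], self.table["meta_rank"]))


def combine_layers(
    rank_vectors: Sequence[RankVector],
    universe: GeneUniverse,
    missing_policy: MissingPolicy = "geometric_mean_available",
    weights: dict[str, float] | None = None,
    gwas_diagnostics: Sequence[GeneSnpAssignment] | None = None,
) -> MetaRankTable:
    """Integrate per-layer rank vectors into a :class:`MetaRankTable`.

    Default policy ``geometric_mean_available``:
    meta_score(g) = (Π over layers scoring g of normalized_rank(g))^(1/k_g),
    with k_g the number of layers scoring g. ``worst_rank`` fills missing
    layers with normalized rank 1.0 and divides by the total layer count.
    Optional per-layer ``weights`` act as exponents (defaults 1, the
    equal-weight integration used throughout). Sorting is ascending by
    meta_score with ties broken by larger n_layers_scored, then
    lexicographic gene_id; the output is fully deterministic.
    """
    if not rank_vectors:
        raise ValueError("combine_layers requires at least one rank vector")
    names = [rv.layer_name for rv in rank_vectors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate layer names: {names}")
    gene_ids = universe.gene_ids
    norm = pd.DataFrame(
        {rv.layer_name: pd.Series(rv.normalized) for rv in rank_vectors},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    w = np.array([float((weights or {}).get(name, 1.0)) for name in names])
    if np.any(w <= 0):
        raise ValueError("layer weights must be positive")

    log_norm = np.log(norm.to_numpy(dtype=float))  # NaN propagates for missing
    scored_mask = ~np.isnan(log_norm)
    n_layers_scored = scored_mask.sum(axis=1)
    if missing_policy == "geometric_mean_available":
        weight_sum = (scored_mask * w).sum(axis=1)
        total = np.nansum(log_norm * w, axis=1)
    elif missing_policy == "worst_rank":
        weight_sum = np.full(len(gene_ids), w.sum())
        total = np.nansum(log_norm * w, axis=1)  # log(1.0) = 0 for missing
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        meta_score = np.exp(total / np.where(weight_sum > 0, weight_sum, np.nan))

    frame = norm.add_prefix("rank_")
    frame.insert(0, "meta_score", meta_score)
    frame["n_layers_scored"] = n_layers_scored
    unscored = frame.index[n_layers_scored == 0].tolist()
    frame = frame[frame["n_layers_scored"] > 0].reset_index()
    frame = frame.sort_values(
        by=["meta_score", "n_layers_scored", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.insert(1, "meta_rank", np.arange(1, len(frame) + 1))

    if gwas_diagnostics is not None:
        diag = pd.DataFrame(
            [
                {
                    "gene_id": a.gene_id,
                    "n_snps": a.n_snps,
                    "best_snp": a.best_snp,
                    "best_p": a.best_p,
                    "m_eff": a.m_eff,
                }
                for a in gwas_diagnostics
            ]
        )
        frame = frame.merge(diag, on="gene_id", how="left")

    columns = ["gene_id", "meta_rank", "meta_score", "n_layers_scored"]
    columns += [f"rank_{name}" for name in names]
    columns += [c for c in GWAS_DIAG_COLUMNS if c in frame.columns]
    return MetaRankTable(
        table=frame[columns], layer_names=names, unscored=sorted(unscored)
    )
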