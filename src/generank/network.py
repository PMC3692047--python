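"""Protein-interaction guilt-by-association scoring.

A gene is scored by its product's propensity to interact with a seed set of
known phenotype genes: the sum of edge confidences to distinct seed
neighbors in a confidence-weighted, undirected interaction network. Direct
neighbors only — no diffusion; the scoring rule is deliberately simple and
pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .core import EvidenceLayer, GeneUniverse, MappingResult, map_gene_ids


class InteractionNetwork:
    """Undirected interaction network with per-edge confidence in (0, 1].

    Self-loops are dropped; duplicate edges (in either orientation) collapse
    to the maximum confidence seen.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]) -> None:
        self.graph = nx.Graph()
        for a, b, conf in edges:
            if a == b:
                continue
            if not 0.0 < conf <= 1.0:
                raise ValueError(
                    f"edge ({a}, {b}): confidence {conf} outside (0, 1]"
                )
            if self.graph.has_edge(a, b):
                if conf > self.graph[a][b]["confidence"]:
                    self.graph[a][b]["confidence"] = conf
            else:
                self.graph.add_edge(a, b, confidence=conf)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (a, b, d["confidence"]) for a, b, d in self.graph.edges(data=True)
        ]

    def filtered(self, min_confidence: float) -> "InteractionNetwork":
        """Copy keeping only edges with confidence >= min_confidence."""
        if not 0.0 <= min_confidence <= 1.0:
            raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
        return InteractionNetwork(
            (a, b, c) for a, b, c in self.edges() if c >= min_confidence
        )

    def neighbors(self, gene: str) -> dict[str, float]:
        if gene not in self.graph:
            return {}
        return {n: self.graph[gene][n]["confidence"] for n in self.graph[gene]}


@dataclass
class SeedSet:
    """Seed genes mapped into the universe."""

    gene_ids: set[str]
    mapping: MappingResult | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("seed set is empty after identifier mapping")

    @classmethod
    def from_raw_ids(
        cls,
        raw_ids: Sequence[str],
        universe: GeneUniverse,
        nomenclature: str = "auto",
    ) -> "SeedSet":
        result = map_gene_ids(raw_ids, nomenclature, universe)
        if not result.mapped:
            raise ValueError(
                f"no seed gene could be mapped into the universe "
                f"(unmapped: {result.unmapped[:5]})"
            )
        return cls(gene_ids=set(result.mapped.values()), mapping=result)


def neighbor_association_score(
    gene: str,
    network: InteractionNetwork,
    seeds: SeedSet,
) -> float:
    """Sum of edge confidences from ``gene`` to its distinct seed neighbors.

    A gene absent from the network scores 0; a seed gene is scored by the
    same rule (its own membership adds nothing).
    """
    return sum(
        conf
        for neighbor, conf in network.neighbors(gene).items()
        if neighbor in seeds.gene_ids
    )


def network_layer_scores(
    network: InteractionNetwork,
    seeds: SeedSet,
    universe: GeneUniverse,
    min_confidence: float = 0.0,
    use_confidence: bool = True,
) -> EvidenceLayer:
    """Guilt-by-association layer: every universe gene scored (descending).

    Edges below ``min_confidence`` are dropped before scoring. With
    ``use_confidence=False`` each qualifying seed neighbor counts 1 instead of
    its edge confidence (raw neighbor-count mode).
    """
    net = network.filtered(min_confidence)
    if not use_confidence:
        net = InteractionNetwork((a, b, 1.0) for a, b, _ in net.edges())
    scores = {
        gene_id: neighbor_association_score(gene_id, net, seeds)
        for gene_id in universe.gene_ids
    }
    return EvidenceLayer(name="network", scores=scores, direction="descending")
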