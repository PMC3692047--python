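"""Gene universe, identifier mapping and the rank machinery shared by every evidence layer.

Every evidence source (GWAS, literature, network, intervals, custom scores) is
reduced to an :class:`EvidenceLayer` — a per-gene score with a sort direction —
and converted to midranked, normalized ranks by :func:`rank_scores` before
integration. The :class:`GeneUniverse` is the common index all layers score
against: the set of protein-coding genes with coordinates and identifier
synonyms in the three common nomenclatures (Ensembl gene IDs, HGNC symbols,
Entrez gene IDs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

NOMENCLATURES = ("ensembl", "symbol", "entrez")

Direction = Literal["ascending", "descending"]


class GeneUniverseError(ValueError):
    """Raised when a universe cannot be constructed unambiguously."""


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene: canonical id, 1-based inclusive coordinates, synonyms."""

    gene_id: str
    chrom: str
    start: int
    end: int
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id}: chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        for nom in self.synonyms:
            if nom not in NOMENCLATURES:
                raise ValueError(
                    f"gene {self.gene_id}: unknown nomenclature {nom!r} "
                    f"(expected one of {NOMENCLATURES})"
                )


def detect_nomenclature(identifier: str) -> str:
    """Guess the nomenclature of a raw identifier.

    ``ENSG``-prefixed ids route to Ensembl, all-digit ids to Entrez, anything
    else to HGNC symbol.
    """
    ident = identifier.strip()
    if ident.upper().startswith("ENSG"):
        return "ensembl"
    if ident.isdigit():
        return "entrez"
    return "symbol"


class GeneUniverse:
    """The set of genes all layers score against, with an unambiguous synonym index.

    Symbols are indexed case-insensitively; Ensembl and Entrez ids exactly.
    A synonym that would resolve to two different genes is a hard error at
    construction: prioritization integrity depends on unambiguous indexing.
    """

    def __init__(self, genes: Iterable[GeneRecord]) -> None:
        self.genes: list[GeneRecord] = list(genes)
        if not self.genes:
            raise GeneUniverseError("a universe requires at least one gene")
        self._by_id: dict[str, GeneRecord] = {}
        # one exact-match index per nomenclature; symbols keyed upper-case
        self._index: dict[str, dict[str, str]] = {nom: {} for nom in NOMENCLATURES}
        for gene in self.genes:
            if gene.gene_id in self._by_id:
                raise GeneUniverseError(f"duplicate gene_id {gene.gene_id!r}")
            self._by_id[gene.gene_id] = gene
        for gene in self.genes:
            for nom, ident in gene.synonyms.items():
                if not ident:
                    continue
                key = ident.upper() if nom == "symbol" else ident
                owner = self._index[nom].get(key)
                if owner is not None and owner != gene.gene_id:
                    raise GeneUniverseError(
                        f"ambiguous {nom} synonym {ident!r}: "
                        f"maps to both {owner!r} and {gene.gene_id!r}"
                    )
                self._index[nom][key] = gene.gene_id

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def get(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chrom == chrom]

    def lookup(self, identifier: str, nomenclature: str = "auto") -> str | None:
        """Resolve ``identifier`` to a canonical gene_id, or None if unknown."""
        ident = identifier.strip()
        if not ident:
            return None
        nom = detect_nomenclature(ident) if nomenclature == "auto" else nomenclature
        if nom not in NOMENCLATURES:
            raise ValueError(f"unknown nomenclature {nomenclature!r}")
        key = ident.upper() if nom == "symbol" else ident
        hit = self._index[nom].get(key)
        if hit is not None:
            return hit
        # canonical ids resolve under any nomenclature
        if ident in self._by_id:
            return ident
        return None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneUniverse":
        """Build a universe from a gene annotation table.

        Expected columns: gene_id, chrom, start, end and optionally ensembl,
        symbol, entrez (empty cells allowed for synonyms).
        """
        required = {"gene_id", "chrom", "start", "end"}
        missing = required - set(frame.columns)
        if missing:
            raise GeneUniverseError(
                f"gene annotation table missing columns: {sorted(missing)}"
            )
        genes = []
        for row in frame.itertuples(index=False):
            synonyms = {}
            for nom in NOMENCLATURES:
                value = getattr(row, nom, None)
                if value is not None and not pd.isna(value) and str(value).strip():
                    synonyms[nom] = str(value).strip()
            genes.append(
                GeneRecord(
                    gene_id=str(row.gene_id),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    synonyms=synonyms,
                )
            )
        return cls(genes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            row = {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for nom in NOMENCLATURES:
                row[nom] = g.synonyms.get(nom, "")
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class MappingResult:
    """Outcome of mapping raw identifiers into a universe."""

    mapped: dict[str, str]
    unmapped: list[str]
    warning: str | None = None


def map_gene_ids(
    raw_ids: Iterable[str],
    nomenclature: str,
    universe: GeneUniverse,
) -> MappingResult:
    """Map raw identifiers (any supported nomenclature) to canonical gene ids.

    ``nomenclature='auto'`` detects the route per id (``ENSG…`` → ensembl,
    all-digits → entrez, otherwise symbol). Every input id is either mapped or
    reported unmapped; more than 50% unmapped raises a warning in the result,
    not an error.
    """
    ids = list(raw_ids)
    if not ids:
        raise ValueError("cannot map an empty identifier list")
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for raw in ids:
        hit = universe.lookup(raw, nomenclature)
        if hit is None:
            unmapped.append(raw)
        else:
            mapped[raw] = hit
    warning = None
    if len(unmapped) > len(ids) / 2:
        warning = (
            f"{len(unmapped)}/{len(ids)} identifiers could not be mapped "
            f"(nomenclature={nomenclature})"
        )
        logger.warning(warning)
    return MappingResult(mapped=mapped, unmapped=unmapped, warning=warning)


@dataclass
class EvidenceLayer:
    """Per-gene raw scores for one evidence source.

    ``direction='ascending'`` means smaller is better (P-values);
    ``'descending'`` means larger is better (similarities, association scores).
    """

    name: str
    scores: dict[str, float]
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction not in ("ascending", "descending"):
            raise ValueError(f"layer {self.name!r}: invalid direction {self.direction!r}")
        for gene_id, score in self.scores.items():
            if not math.isfinite(score):
                raise ValueError(
                    f"layer {self.name!r}: non-finite score for gene {gene_id!r}"
                )

    def validate_universe(self, universe: GeneUniverse) -> None:
        strays = [g for g in self.scores if g not in universe]
        if strays:
            raise ValueError(
                f"layer {self.name!r}: genes not in universe: {strays[:5]}"
            )


@dataclass
class RankVector:
    """Midranked ranks and normalized ranks (rank / N) for one layer."""

    layer_name: str
    ranks: dict[str, float]
    normalized: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.ranks)


def rank_scores(layer: EvidenceLayer) -> RankVector:
    """Convert an evidence layer to midranked, normalized ranks.

    The best gene gets rank 1 (or the midrank of the tied best group); tied
    scores receive the mean of the positions they span, so the rank sum is
    always N(N+1)/2. Normalized rank = rank / N, in (0, 1].
    """
    if not layer.scores:
        raise ValueError(f"layer {layer.name!r} is empty; cannot rank")
    genes = sorted(layer.scores)
    values = [layer.scores[g] for g in genes]
    if layer.direction == "descending":
        values = [-v for v in values]
    ranks = rankdata(values, method="average")
    n = len(genes)
    rank_map = {g: float(r) for g, r in zip(genes, ranks)}
    norm_map = {g: float(r) / n for g, r in zip(genes, ranks)}
    return RankVector(layer_name=layer.name, ranks=rank_map, normalized=norm_map)
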