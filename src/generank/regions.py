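"""Chromosomal-interval and custom gene-score evidence layers.

Linkage intervals and copy-number variants arrive as coordinate regions
("chr4:300,123-404,567"); genes overlapping any region form the top tier and
everything else the bottom tier, so downstream midranking weights the
overlapped genes collectively higher. Custom layers ingest user gene-score
tables (expression levels, rare-variant association P-values, binary
causality lists) in any supported nomenclature.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import Direction, EvidenceLayer, GeneUniverse, MappingResult, map_gene_ids

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(
    r"(?:chr)?([A-Za-z0-9_]+):([0-9][0-9,]*)-([0-9][0-9,]*)", re.IGNORECASE
)


@dataclass(frozen=True)
class GenomicRegion:
    """A chromosomal interval, 1-based and inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        chrom = self.chrom.strip()
        if not chrom:
            raise ValueError("region chromosome must be non-empty")
        if not chrom.lower().startswith("chr"):
            chrom = f"chr{chrom}"
        object.__setattr__(self, "chrom", chrom)
        if self.start < 1:
            raise ValueError(f"region start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} > end {self.end}"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def parse_region_string(text: str) -> GenomicRegion:
    """Parse a UCSC-style region string, e.g. ``chr4:300,123-404,567``.

    Thousands separators are permitted and the ``chr`` prefix is optional
    (it is normalized onto the stored chromosome label).
    """
    m = _REGION_RE.fullmatch(text.strip())
    if m is None:
        raise ValueError(
            f"malformed region string {text!r}; expected chrom:start-end, "
            "e.g. chr4:300,123-404,567"
        )
    chrom, start, end = m.groups()
    return GenomicRegion(
        chrom=chrom, start=int(start.replace(",", "")), end=int(end.replace(",", ""))
    )


def format_region(region: GenomicRegion) -> str:
    return str(region)


def _norm_chrom(chrom: str) -> str:
    label = chrom.strip().lower()
    return label[3:] if label.startswith("chr") else label


def region_layer_scores(
    regions: Sequence[GenomicRegion],
    universe: GeneUniverse,
) -> EvidenceLayer:
    """Two-tier layer: genes overlapping any region score 1, all others 0.

    Overlap is any shared base on matching chromosomes (1-based inclusive):
    gene.start <= region.end and region.start <= gene.end.
    """
    if not regions:
        raise ValueError("region layer requires at least one region")
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for region in regions:
        by_chrom.setdefault(_norm_chrom(region.chrom), []).append(region)
    scores: dict[str, float] = {}
    for gene in universe:
        hits = by_chrom.get(_norm_chrom(gene.chrom), ())
        overlaps = any(gene.start <= r.end and r.start <= gene.end for r in hits)
        scores[gene.gene_id] = 1.0 if overlaps else 0.0
    return EvidenceLayer(name="regions", scores=scores, direction="descending")


@dataclass
class CustomLayerSpec:
    """A user gene-score table destined to become one evidence layer.

    In ``binary_mode`` the scores are ignored: listed genes form tier 1 and
    every other gene in the universe tier 2 (listed genes outrank all others).
    """

    name: str
    table: Mapping[str, float | None]
    nomenclature: str = "auto"
    direction: Direction | None = None
    binary_mode: bool = False

    def __post_init__(self) -> None:
        if not self.table:
            raise ValueError(f"custom layer {self.name!r}: empty score table")
        if self.direction is None and not self.binary_mode:
            logger.warning(
                "custom layer %r: no direction given, defaulting to ascending",
                self.name,
            )
            self.direction = "ascending"


@dataclass
class CustomLayerResult:
    layer: EvidenceLayer
    mapping: MappingResult
    n_duplicates: int = 0


def load_custom_layer(
    spec: CustomLayerSpec,
    universe: GeneUniverse,
) -> CustomLayerResult:
    """Map a custom gene-score table into the universe and build its layer.

    Duplicate raw ids resolving to the same gene keep the best score for the
    stated direction (minimum when ascending, maximum when descending) and
    the collision is logged. Zero mapped genes is an error; unmapped ids are
    reported in the result.
    """
    mapping = map_gene_ids(list(spec.table), spec.nomenclature, universe)
    if not mapping.mapped:
        raise ValueError(
            f"custom layer {spec.name!r}: no identifier mapped into the "
            f"universe (first unmapped: {mapping.unmapped[:5]})"
        )
    if spec.binary_mode:
        listed = set(mapping.mapped.values())
        scores = {g: (1.0 if g in listed else 0.0) for g in universe.gene_ids}
        layer = EvidenceLayer(name=spec.name, scores=scores, direction="descending")
        return CustomLayerResult(layer=layer, mapping=mapping)
    keep_best = min if spec.direction == "ascending" else max
    scores: dict[str, float] = {}
    n_duplicates = 0
    for raw_id, gene_id in mapping.mapped.items():
        value = spec.table[raw_id]
        if value is None:
            raise ValueError(
                f"custom layer {spec.name!r}: id {raw_id!r} has no score "
                "(use binary_mode for plain gene lists)"
            )
        score = float(value)
        if gene_id in scores:
            n_duplicates += 1
            kept = keep_best(scores[gene_id], score)
            logger.info(
                "custom layer %r: duplicate mapping for %s; keeping %s",
                spec.name, gene_id, kept,
            )
            scores[gene_id] = kept
        else:
            scores[gene_id] = score
    layer = EvidenceLayer(name=spec.name, scores=scores, direction=spec.direction)
    return CustomLayerResult(layer=layer, mapping=mapping, n_duplicates=n_duplicates)
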