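"""Readers and writers for all external formats, run configuration, and the pipeline.

Everything is delimited text; GWAS summary statistics may additionally arrive
gzip-, zip- or tar-compressed (an archive must contain exactly one member
file). Output tables are TSV with a commented header recording the package
version, a configuration hash, and the run seed — and no timestamps, so
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _stdio
import json
import logging
import tarfile
import time
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import scipy.sparse as sp
import yaml

from . import __version__
from .core import EvidenceLayer, GeneUniverse, rank_scores
from .gwas import DEFAULT_WINDOW_BP, LdPanel, SnpRecord, gwas_layer_scores
from .integrate import MetaRankTable, combine_layers
from .network import InteractionNetwork, SeedSet, network_layer_scores
from .regions import (
    CustomLayerSpec,
    GenomicRegion,
    load_custom_layer,
    parse_region_string,
    region_layer_scores,
)
from .text import SparseCorpus, text_layer_scores

logger = logging.getLogger(__name__)

DEFAULT_GWAS_COLUMNS = {"snp": "SNP", "chrom": "CHR", "pos": "POS", "pvalue": "P"}
CUSTOM_LAYER_SOFT_CAP = 5


# ---------------------------------------------------------------------------
# low-level text access with transparent decompression

def open_text(path: str | Path):
    """Open a possibly compressed text file for reading.

    ``.gz`` decompresses in place; ``.zip`` and ``.tar``/``.tar.gz`` archives
    must contain exactly one member file, whose content is returned.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".tar", ".tar.gz", ".tgz")):
        with tarfile.open(path, "r:*") as tar:
            members = [m for m in tar.getmembers() if m.isfile()]
            if len(members) != 1:
                raise ValueError(
                    f"{path}: archive must contain exactly one file, found {len(members)}"
                )
            data = tar.extractfile(members[0]).read()
        return _stdio.StringIO(data.decode("utf-8"))
    if name.endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            members = [n for n in zf.namelist() if not n.endswith("/")]
            if len(members) != 1:
                raise ValueError(
                    f"{path}: archive must contain exactly one file, found {len(members)}"
                )
            data = zf.read(members[0])
        return _stdio.StringIO(data.decode("utf-8"))
    if name.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _sniff_delimiter(header: str) -> str | None:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return None  # any whitespace


# ---------------------------------------------------------------------------
# GWAS summary statistics

@dataclass
class GwasReadReport:
    n_records: int
    n_skipped: int
    n_duplicates: int


def read_gwas_summary(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> tuple[list[SnpRecord], GwasReadReport]:
    """Read GWAS summary statistics from (possibly compressed) delimited text.

    ``column_map`` renames the expected logical columns (snp, chrom, pos,
    pvalue) to the file's header names; defaults are SNP, CHR, POS, P
    (matched case-insensitively). Malformed rows are skipped and counted;
    duplicate SNP ids keep the smallest P-value.
    """
    colmap = {**DEFAULT_GWAS_COLUMNS, **(column_map or {})}
    with open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip() for h in (lines[0].split(delim) if delim else lines[0].split())]
    lookup = {h.lower(): i for i, h in enumerate(header)}
    indices = {}
    for logical, name in colmap.items():
        if name.lower() not in lookup:
            raise ValueError(f"{path}: missing column {name!r} (for {logical})")
        indices[logical] = lookup[name.lower()]

    records: dict[str, SnpRecord] = {}
    n_skipped = 0
    n_duplicates = 0
    for line in lines[1:]:
        fields = line.split(delim) if delim else line.split()
        try:
            snp_id = fields[indices["snp"]].strip()
            chrom = fields[indices["chrom"]].strip()
            pos = int(fields[indices["pos"]])
            pvalue = float(fields[indices["pvalue"]])
            if not snp_id or not chrom:
                raise ValueError("empty id or chromosome")
            record = SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, pvalue=pvalue)
        except (IndexError, ValueError):
            n_skipped += 1
            continue
        if snp_id in records:
            n_duplicates += 1
            if record.pvalue < records[snp_id].pvalue:
                records[snp_id] = record
        else:
            records[snp_id] = record
    if not records:
        raise ValueError(f"{path}: no valid SNP rows")
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    if n_duplicates:
        logger.warning("%s: %d duplicate SNP ids (kept smallest P)", path, n_duplicates)
    report = GwasReadReport(
        n_records=len(records), n_skipped=n_skipped, n_duplicates=n_duplicates
    )
    return list(records.values()), report


def write_gwas_summary(path: str | Path, snps: Sequence[SnpRecord]) -> None:
    frame = pd.DataFrame(
        {
            "SNP": [s.snp_id for s in snps],
            "CHR": [s.chrom for s in snps],
            "POS": [s.pos for s in snps],
            "P": [s.pvalue for s in snps],
        }
    )
    path = Path(path)
    if path.name.endswith(".gz"):
        with gzip.open(path, "wt", encoding="utf-8") as handle:
            frame.to_csv(handle, sep="\t", index=False)
    else:
        frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype panel, edge lists, gene lists / scores, universe, regions, corpus

def read_panel(path: str | Path) -> LdPanel:
    """Headered delimited matrix: rows samples, first column sample id, columns SNPs."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "na", ""])
    return LdPanel(
        snp_ids=[str(c) for c in frame.columns],
        genotypes=frame.to_numpy(dtype=float),
    )


def write_panel(path: str | Path, panel: LdPanel) -> None:
    frame = pd.DataFrame(
        panel.genotypes,
        columns=panel.snp_ids,
        index=[f"S{i:04d}" for i in range(panel.genotypes.shape[0])],
    )
    frame.index.name = "sample"
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Delimited edge list: gene_a, gene_b[, confidence]; confidence defaults 1.0."""
    edges = []
    with open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed edge line {line!r}")
            conf = float(fields[2]) if len(fields) > 2 else 1.0
            edges.append((fields[0], fields[1], conf))
    return InteractionNetwork(edges)


def write_edge_list(path: str | Path, network: InteractionNetwork) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b, conf in sorted(network.edges()):
            handle.write(f"{a}\t{b}\t{conf:.6g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open_text(path) as handle:
        return [ln.strip() for ln in handle if ln.strip() and not ln.startswith("#")]


def write_gene_list(path: str | Path, genes: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_gene_scores(path: str | Path) -> dict[str, float | None]:
    """Two-column (gene, score) or one-column (gene) delimited table.

    One-column input yields all-None scores, implying binary mode downstream.
    """
    table: dict[str, float | None] = {}
    with open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            table[fields[0]] = float(fields[1]) if len(fields) > 1 else None
    if not table:
        raise ValueError(f"{path}: empty gene-score table")
    return table


def read_universe(path: str | Path) -> GeneUniverse:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    return GeneUniverse.from_frame(frame)


def write_universe(path: str | Path, universe: GeneUniverse) -> None:
    universe.to_frame().to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[GenomicRegion]:
    """Region strings (one per line) or 3-column BED (0-based half-open, converted)."""
    path = Path(path)
    regions = []
    with open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if ":" in line:
                regions.append(parse_region_string(line))
            else:
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}: malformed region line {line!r}")
                # BED 0-based half-open -> 1-based inclusive
                regions.append(
                    GenomicRegion(
                        chrom=fields[0], start=int(fields[1]) + 1, end=int(fields[2])
                    )
                )
    if not regions:
        raise ValueError(f"{path}: no regions found")
    return regions


def write_regions(path: str | Path, regions: Sequence[GenomicRegion]) -> None:
    Path(path).write_text(
        "".join(f"{r}\n" for r in regions), encoding="utf-8"
    )


def read_corpus(
    counts_path: str | Path,
    doc_genes_path: str | Path,
    doc_terms_path: str | Path,
) -> SparseCorpus:
    """Corpus from count triples (doc_id, token, count) and two annotation tables."""
    triples = pd.read_csv(
        counts_path, sep="\t", names=["doc_id", "token", "count"], dtype=str, header=0
    )
    triples["count"] = triples["count"].astype(float)
    doc_ids = sorted(triples["doc_id"].unique())
    vocab = sorted(triples["token"].unique())
    doc_index = {d: i for i, d in enumerate(doc_ids)}
    tok_index = {t: i for i, t in enumerate(vocab)}
    counts = sp.csr_matrix(
        (
            triples["count"].to_numpy(),
            (
                triples["doc_id"].map(doc_index).to_numpy(),
                triples["token"].map(tok_index).to_numpy(),
            ),
        ),
        shape=(len(doc_ids), len(vocab)),
    )

    def _read_pairs(path: str | Path) -> dict[str, list[str]]:
        frame = pd.read_csv(path, sep="\t", dtype=str, header=0)
        frame.columns = ["doc_id", "entity"]
        out: dict[str, list[str]] = {}
        for doc_id, entity in frame.itertuples(index=False):
            out.setdefault(doc_id, []).append(entity)
        return out

    return SparseCorpus(
        doc_ids=doc_ids,
        vocab=vocab,
        counts=counts,
        doc_genes=_read_pairs(doc_genes_path),
        doc_terms=_read_pairs(doc_terms_path),
    )


def write_corpus(
    corpus: SparseCorpus,
    counts_path: str | Path,
    doc_genes_path: str | Path,
    doc_terms_path: str | Path,
) -> None:
    coo = corpus.counts.tocoo()
    rows = sorted(
        (corpus.doc_ids[i], corpus.vocab[j], v)
        for i, j, v in zip(coo.row, coo.col, coo.data)
    )
    with open(counts_path, "w", encoding="utf-8") as handle:
        handle.write("doc_id\ttoken\tcount\n")
        for doc_id, token, value in rows:
            handle.write(f"{doc_id}\t{token}\t{value:g}\n")
    for path, mapping, colname in (
        (doc_genes_path, corpus.doc_genes, "gene_id"),
        (doc_terms_path, corpus.doc_terms, "term_id"),
    ):
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"doc_id\t{colname}\n")
            for doc_id in sorted(mapping):
                for entity in mapping[doc_id]:
                    handle.write(f"{doc_id}\t{entity}\n")


# ---------------------------------------------------------------------------
# meta-rank table round-trip

def write_meta_rank(
    path: str | Path,
    meta: MetaRankTable,
    config_hash: str = "",
    seed: int | None = None,
) -> None:
    """Write the integrated table as TSV with a commented provenance header."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# generank {__version__}\n")
        handle.write(f"# config_hash={config_hash}\n")
        handle.write(f"# seed={seed if seed is not None else 'NA'}\n")
        handle.write(f"# layers={','.join(meta.layer_names)}\n")
        meta.table.to_csv(handle, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_meta_rank(path: str | Path) -> MetaRankTable:
    layer_names: list[str] = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            if line.startswith("# layers="):
                layer_names = line.strip().split("=", 1)[1].split(",")
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    return MetaRankTable(table=frame, layer_names=layer_names)


# ---------------------------------------------------------------------------
# run configuration and the pipeline

@dataclass
class RunConfig:
    """Validated configuration of one prioritization run (mirrors the CLI flags)."""

    universe: str
    output_prefix: str
    seed: int = 0
    gwas: dict[str, Any] | None = None       # file, window_bp, panel, adjustment, columns
    text: dict[str, Any] | None = None       # counts, doc_genes, doc_terms, terms, logic
    network: dict[str, Any] | None = None    # edges, seeds, min_confidence, nomenclature
    regions: dict[str, Any] | None = None    # file
    custom: list[dict[str, Any]] = field(default_factory=list)
    integration_policy: str = "geometric_mean_available"
    layer_weights: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def enabled_layers(self) -> list[str]:
        enabled = [
            name for name in ("gwas", "text", "network", "regions")
            if getattr(self, name)
        ]
        enabled += [f"custom:{blk.get('name', i)}" for i, blk in enumerate(self.custom)]
        return enabled

    def validate(self) -> None:
        if not self.enabled_layers():
            raise ValueError("configuration enables no evidence layer")
        if len(self.custom) > CUSTOM_LAYER_SOFT_CAP:
            logger.warning(
                "%d custom layers configured (more than the usual cap of %d)",
                len(self.custom), CUSTOM_LAYER_SOFT_CAP,
            )
        paths = [self.universe]
        if self.gwas:
            paths.append(self.gwas["file"])
            if self.gwas.get("panel"):
                paths.append(self.gwas["panel"])
        if self.text:
            paths += [self.text["counts"], self.text["doc_genes"], self.text["doc_terms"]]
        if self.network:
            paths += [self.network["edges"], self.network["seeds"]]
        if self.regions:
            paths.append(self.regions["file"])
        for blk in self.custom:
            paths.append(blk["file"])
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-run accounting: layer sizes, unmapped ids, parameters, timings."""

    seed: int
    config_hash: str
    layers: dict[str, dict[str, Any]] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    n_ranked: int = 0
    n_unscored: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "layers": self.layers,
                "stage_seconds": self.stage_seconds,
                "n_ranked": self.n_ranked,
                "n_unscored": self.n_unscored,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(config: RunConfig) -> tuple[MetaRankTable, RunReport]:
    """Execute every enabled layer, integrate, and write the outputs.

    Any layer failure aborts the run naming the layer, and partially written
    outputs are removed.
    """
    config.validate()
    report = RunReport(seed=config.seed, config_hash=config.digest())
    universe = read_universe(config.universe)
    layers: list[EvidenceLayer] = []
    gwas_diag = None
    current = "universe"

    def _stage(name: str):
        nonlocal current
        current = name
        return time.perf_counter()

    try:
        if config.gwas:
            t0 = _stage("gwas")
            snps, gwas_report = read_gwas_summary(
                config.gwas["file"], config.gwas.get("columns")
            )
            panel = read_panel(config.gwas["panel"]) if config.gwas.get("panel") else None
            result = gwas_layer_scores(
                snps,
                universe,
                window_bp=int(config.gwas.get("window_bp", DEFAULT_WINDOW_BP)),
                panel=panel,
                adjustment=config.gwas.get("adjustment", "sidak"),
            )
            layers.append(result.layer)
            gwas_diag = result.assignments
            report.layers["gwas"] = {
                "n_genes": len(result.layer.scores),
                "n_snps": gwas_report.n_records,
                "n_unmapped_snps": result.n_unmapped_snps,
                "n_skipped_rows": gwas_report.n_skipped,
                "window_bp": int(config.gwas.get("window_bp", DEFAULT_WINDOW_BP)),
                "adjustment": config.gwas.get("adjustment", "sidak"),
                "ld_panel": bool(config.gwas.get("panel")),
            }
            report.stage_seconds["gwas"] = time.perf_counter() - t0

        if config.text:
            t0 = _stage("text")
            corpus = read_corpus(
                config.text["counts"], config.text["doc_genes"], config.text["doc_terms"]
            )
            layer = text_layer_scores(
                corpus,
                list(config.text["terms"]),
                config.text.get("logic", "OR"),
                universe,
            )
            layers.append(layer)
            report.layers["text"] = {
                "n_genes": len(layer.scores),
                "terms": list(config.text["terms"]),
                "logic": config.text.get("logic", "OR"),
                "n_docs": corpus.n_docs,
            }
            report.stage_seconds["text"] = time.perf_counter() - t0

        if config.network:
            t0 = _stage("network")
            net = read_edge_list(config.network["edges"])
            seeds = SeedSet.from_raw_ids(
                read_gene_list(config.network["seeds"]),
                universe,
                nomenclature=config.network.get("nomenclature", "auto"),
            )
            layer = network_layer_scores(
                net,
                seeds,
                universe,
                min_confidence=float(config.network.get("min_confidence", 0.0)),
            )
            layers.append(layer)
            report.layers["network"] = {
                "n_genes": len(layer.scores),
                "n_edges": net.n_edges,
                "n_seeds": len(seeds.gene_ids),
                "n_unmapped_seeds": len(seeds.mapping.unmapped) if seeds.mapping else 0,
                "min_confidence": float(config.network.get("min_confidence", 0.0)),
            }
            report.stage_seconds["network"] = time.perf_counter() - t0

        if config.regions:
            t0 = _stage("regions")
            regions = read_regions(config.regions["file"])
            layer = region_layer_scores(regions, universe)
            layers.append(layer)
            report.layers["regions"] = {
                "n_genes": len(layer.scores),
                "n_regions": len(regions),
                "n_overlapping": int(sum(layer.scores.values())),
            }
            report.stage_seconds["regions"] = time.perf_counter() - t0

        for i, blk in enumerate(config.custom):
            name = blk.get("name", f"custom{i + 1}")
            t0 = _stage(name)
            table = read_gene_scores(blk["file"])
            binary = bool(blk.get("binary_mode", all(v is None for v in table.values())))
            spec = CustomLayerSpec(
                name=name,
                table=table,
                nomenclature=blk.get("nomenclature", "auto"),
                direction=blk.get("direction"),
                binary_mode=binary,
            )
            result = load_custom_layer(spec, universe)
            layers.append(result.layer)
            report.layers[name] = {
                "n_genes": len(result.layer.scores),
                "n_unmapped": len(result.mapping.unmapped),
                "unmapped": result.mapping.unmapped[:20],
                "binary_mode": binary,
                "direction": spec.direction,
                "n_duplicates": result.n_duplicates,
            }
            report.stage_seconds[name] = time.perf_counter() - t0

        t0 = _stage("integrate")
        rank_vectors = [rank_scores(layer) for layer in layers]
        meta = combine_layers(
            rank_vectors,
            universe,
            missing_policy=config.integration_policy,
            weights=config.layer_weights or None,
            gwas_diagnostics=gwas_diag,
        )
        report.stage_seconds["integrate"] = time.perf_counter() - t0
        report.n_ranked = len(meta.table)
        report.n_unscored = len(meta.unscored)
    except Exception as exc:
        for suffix in (".meta_rank.tsv", ".report.json"):
            Path(config.output_prefix + suffix).unlink(missing_ok=True)
        raise RuntimeError(f"layer {current!r} failed: {exc}") from exc

    write_meta_rank(
        config.output_prefix + ".meta_rank.tsv",
        meta,
        config_hash=report.config_hash,
        seed=config.seed,
    )
    Path(config.output_prefix + ".report.json").write_text(
        report.to_json() + "\n", encoding="utf-8"
    )
    return meta, report
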