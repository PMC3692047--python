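"""Literature-based gene scoring.

Genes and phenotype terms are represented as word vectors accumulated from a
pre-tokenized document–term corpus: the vector of an entity is the sum of the
token counts of all documents annotated to it. Vectors are reweighted by
tf-idf to damp publication bias (heavily mentioned, uninformative tokens),
unit-normalized, and compared by cosine similarity. Multiple query terms
combine with logical OR (elementwise max) or AND (elementwise min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .core import EvidenceLayer, GeneUniverse

Logic = Literal["AND", "OR"]


@dataclass
class SparseCorpus:
    """A pre-tokenized document–term corpus with gene and term annotations.

    ``counts`` is a document × token sparse matrix of non-negative integer
    counts; ``doc_genes`` / ``doc_terms`` annotate documents with the genes
    they mention and the phenotype terms assigned to them.
    """

    doc_ids: list[str]
    vocab: list[str]
    counts: sp.csr_matrix
    doc_genes: Mapping[str, Sequence[str]]
    doc_terms: Mapping[str, Sequence[str]]
    _doc_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.doc_ids), len(self.vocab)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.doc_ids)} docs × {len(self.vocab)} tokens"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("corpus counts must be non-negative")
        self._doc_index = {d: i for i, d in enumerate(self.doc_ids)}
        for mapping, what in ((self.doc_genes, "doc_genes"), (self.doc_terms, "doc_terms")):
            unknown = [d for d in mapping if d not in self._doc_index]
            if unknown:
                raise ValueError(f"{what} references unknown doc_id {unknown[0]!r}")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def doc_index(self, doc_id: str) -> int:
        return self._doc_index[doc_id]

    def annotated_genes(self) -> list[str]:
        return sorted({g for genes in self.doc_genes.values() for g in genes})

    def annotated_terms(self) -> list[str]:
        return sorted({t for terms in self.doc_terms.values() for t in terms})


@dataclass
class TermVectorSpace:
    """Sparse entity × token word vectors for genes and phenotype terms."""

    entity_ids: list[str]
    vectors: sp.csr_matrix
    vocab: list[str]
    weighting: Literal["raw", "tfidf"]
    normalized: bool
    zero_entities: set[str]
    n_docs: int
    doc_freq: np.ndarray  # documents containing each token
    _entity_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._entity_index = {e: i for i, e in enumerate(self.entity_ids)}

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._entity_index

    def vector(self, entity_id: str) -> np.ndarray:
        return np.asarray(
            self.vectors[self._entity_index[entity_id]].todense()
        ).ravel()


def build_entity_vectors(
    corpus: SparseCorpus,
    entity_ids: Iterable[str] | None = None,
) -> TermVectorSpace:
    """Accumulate raw word vectors: entity vector = Σ counts of its documents.

    ``entity_ids`` defaults to every gene and term annotated in the corpus;
    pass an explicit list to include entities with no literature, which get
    zero vectors and are flagged in ``zero_entities``.
    """
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    if entity_ids is None:
        entities = corpus.annotated_genes() + [
            t for t in corpus.annotated_terms() if t not in set(corpus.annotated_genes())
        ]
    else:
        entities = list(entity_ids)
    entity_docs: dict[str, list[int]] = {e: [] for e in entities}
    for mapping in (corpus.doc_genes, corpus.doc_terms):
        for doc_id, ents in mapping.items():
            row = corpus.doc_index(doc_id)
            for ent in ents:
                if ent in entity_docs:
                    entity_docs[ent].append(row)
    incidence = sp.lil_matrix((len(entities), corpus.n_docs))
    for i, ent in enumerate(entities):
        for row in entity_docs[ent]:
            incidence[i, row] = 1.0
    vectors = sp.csr_matrix(incidence) @ corpus.counts
    row_norms = np.sqrt(np.asarray(vectors.multiply(vectors).sum(axis=1)).ravel())
    zero = {e for e, nrm in zip(entities, row_norms) if nrm == 0.0}
    doc_freq = np.asarray((corpus.counts > 0).sum(axis=0)).ravel()
    return TermVectorSpace(
        entity_ids=entities,
        vectors=sp.csr_matrix(vectors),
        vocab=list(corpus.vocab),
        weighting="raw",
        normalized=False,
        zero_entities=zero,
        n_docs=corpus.n_docs,
        doc_freq=doc_freq,
    )


def normalize_vectors(space: TermVectorSpace) -> TermVectorSpace:
    """Apply tf-idf weighting and unit-norm scaling to a raw vector space.

    Token weight = raw count × idf with idf = ln(D / d_t); a token present in
    every document gets idf ln(1) = 0 and contributes nothing to any
    similarity. Vectors that become all-zero after weighting stay zero and are
    flagged; their similarity to anything is defined as 0.
    """
    if space.weighting != "raw" or space.normalized:
        raise ValueError("normalize_vectors expects a raw, unnormalized space")
    with np.errstate(divide="ignore"):
        idf = np.where(space.doc_freq > 0, np.log(space.n_docs / np.maximum(space.doc_freq, 1)), 0.0)
    weighted = sp.csr_matrix(space.vectors @ sp.diags(idf))
    norms = np.sqrt(np.asarray(weighted.multiply(weighted).sum(axis=1)).ravel())
    zero = set(space.zero_entities) | {
        e for e, nrm in zip(space.entity_ids, norms) if nrm == 0.0
    }
    inv = np.where(norms > 0, 1.0 / np.maximum(norms, 1e-300), 0.0)
    normalized = sp.csr_matrix(sp.diags(inv) @ weighted)
    return TermVectorSpace(
        entity_ids=list(space.entity_ids),
        vectors=normalized,
        vocab=list(space.vocab),
        weighting="tfidf",
        normalized=True,
        zero_entities=zero,
        n_docs=space.n_docs,
        doc_freq=space.doc_freq.copy(),
    )


def cosine_similarity(v: np.ndarray, w: np.ndarray) -> float:
    """Cosine of the angle between two word vectors; 0 if either is zero."""
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError(f"dimension mismatch: {v.shape} vs {w.shape}")
    nv = np.linalg.norm(v)
    nw = np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        return 0.0
    return float(max(0.0, np.dot(v, w) / (nv * nw)))


def combine_terms(
    per_term: Mapping[str, Mapping[str, float]],
    logic: Logic,
) -> dict[str, float]:
    """Combine per-term similarity mappings: OR = elementwise max, AND = min."""
    if not per_term:
        raise ValueError("combine_terms requires at least one term")
    if logic not in ("AND", "OR"):
        raise ValueError(f"logic must be 'AND' or 'OR', got {logic!r}")
    terms = list(per_term)
    gene_sets = [set(per_term[t]) for t in terms]
    if any(s != gene_sets[0] for s in gene_sets[1:]):
        raise ValueError("all per-term mappings must cover the same gene set")
    reduce_fn = max if logic == "OR" else min
    return {
        gene: reduce_fn(per_term[t][gene] for t in terms)
        for gene in sorted(gene_sets[0])
    }


def text_layer_scores(
    corpus: SparseCorpus,
    term_ids: Sequence[str],
    logic: Logic,
    universe: GeneUniverse,
) -> EvidenceLayer:
    """Score every universe gene by combined cosine similarity to the query terms.

    Genes with no literature (zero vectors) score 0, the worst possible under
    the descending direction.
    """
    known_terms = corpus.annotated_terms()
    unknown = [t for t in term_ids if t not in known_terms]
    if unknown:
        raise KeyError(
            f"unknown term id(s) {unknown}; valid terms: {known_terms}"
        )
    gene_ids = universe.gene_ids
    entities = gene_ids + [t for t in term_ids if t not in set(gene_ids)]
    space = normalize_vectors(build_entity_vectors(corpus, entity_ids=entities))
    gene_rows = sp.csr_matrix(space.vectors[: len(gene_ids)])
    per_term: dict[str, dict[str, float]] = {}
    for term in term_ids:
        tvec = space.vector(term)
        sims = np.maximum(np.asarray((gene_rows @ tvec)).ravel(), 0.0)
        per_term[term] = {g: float(s) for g, s in zip(gene_ids, sims)}
    combined = combine_terms(per_term, logic)
    return EvidenceLayer(name="text", scores=combined, direction="descending")
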