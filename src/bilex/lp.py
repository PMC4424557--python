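"""Co-occurrence graph construction and clamped label propagation.

Vertices are the terms of one language; an edge joins two terms that
co-occur in at least one sentence, weighted by the cosine similarity of
their context vectors (co-occurrence frequency is available behind a
flag).  Seed vertices carry clamped one-hot labels over the seed-pair
dimensions; all other vertices start uniform and are iteratively
replaced by the weight-normalised average of their neighbours' labels.
Because the label spaces of the two languages are both indexed by seed
pairs, converged labels are directly comparable across languages by
cosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from bilex.context import (
    CandidateRanking,
    ContextVector,
    candidate_sort_key,
    cosine,
)
from bilex.corpus_io import AnnotatedCorpus, SeedLexicon, TermType, VocabEntry

__all__ = [
    "CooccurrenceGraph",
    "LabelMatrix",
    "LPModel",
    "SingularSystemError",
    "build_graph",
    "fixed_point_oracle",
    "init_labels",
    "propagate",
    "rank_lp",
]


class SingularSystemError(ValueError):
    """A non-seed component with edges but no seed has no unique fixed point."""


@dataclass
class CooccurrenceGraph:
    """Undirected weighted term graph with designated seed vertices.

    ``seed_dims`` maps each seed vertex to the tuple of seed-pair
    dimensions it participates in (usually one; a term appearing in
    several seed pairs owns several dimensions but remains one vertex).
    """

    vertices: list[TermType]
    weights: sp.csr_matrix  # symmetric, zero diagonal
    seed_dims: dict[TermType, tuple[int, ...]]
    n_dims: int
    vertex_index: dict[TermType, int] = field(init=False)

    def __post_init__(self) -> None:
        self.vertex_index = {t: i for i, t in enumerate(self.vertices)}
        if self.weights.shape != (len(self.vertices),) * 2:
            raise ValueError("weight matrix shape does not match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def is_seed(self, term: TermType) -> bool:
        return term in self.seed_dims

    def seed_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_vertices, dtype=bool)
        for term in self.seed_dims:
            mask[self.vertex_index[term]] = True
        return mask

    def degree(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


@dataclass
class LabelMatrix:
    """Per-vertex label distributions over seed-pair dimensions."""

    graph: CooccurrenceGraph
    values: np.ndarray  # (n_vertices, n_dims)
    iteration: int = 0

    def label_of(self, term: TermType) -> np.ndarray:
        return self.values[self.graph.vertex_index[term]]


def build_graph(
    vocabulary: dict[TermType, VocabEntry],
    context_vectors: dict[TermType, ContextVector],
    corpus: AnnotatedCorpus,
    lexicon: SeedLexicon,
    edge_weight: str = "cosine",
    side: str | None = None,
) -> CooccurrenceGraph:
    """Build the sentence co-occurrence graph over ``vocabulary`` terms.

    An edge exists iff the two terms co-occur within one sentence at
    least once; its weight is the cosine of their context vectors
    (``edge_weight="cosine"``, default) or the raw co-occurrence count
    (``edge_weight="freq"``).  Zero-weight edges are dropped.
    """
    if not vocabulary:
        raise ValueError("empty vocabulary")
    if edge_weight not in ("cosine", "freq"):
        raise ValueError(f"unknown edge_weight {edge_weight!r}")
    if side is None:
        side = lexicon.side_for_language(corpus.language)

    vertices = sorted(vocabulary)
    index = {t: i for i, t in enumerate(vertices)}

    # sentence co-occurrence counts over distinct term types
    pair_counts: dict[tuple[int, int], int] = {}
    for doc in corpus.documents:
        per_sentence: dict[int, set[int]] = {}
        for occ in doc.term_occurrences:
            term = corpus.term_type(doc, occ)
            if term in index:
                per_sentence.setdefault(occ.sentence_index, set()).add(index[term])
        for terms in per_sentence.values():
            ordered = sorted(terms)
            for a_pos, a in enumerate(ordered):
                for b in ordered[a_pos + 1 :]:
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1

    rows, cols, vals = [], [], []
    for (a, b), count in pair_counts.items():
        if edge_weight == "freq":
            w = float(count)
        else:
            w = cosine(context_vectors[vertices[a]], context_vectors[vertices[b]])
        if w <= 0.0:
            continue
        rows += [a, b]
        cols += [b, a]
        vals += [w, w]
    n = len(vertices)
    weights = sp.csr_matrix(
        (np.array(vals, dtype=float), (rows, cols)), shape=(n, n)
    )

    all_dims = lexicon.dims_by_term(side)
    seed_dims = {t: dims for t, dims in all_dims.items() if t in index}
    return CooccurrenceGraph(
        vertices=vertices,
        weights=weights,
        seed_dims=seed_dims,
        n_dims=lexicon.n,
    )


def _clamped_values(graph: CooccurrenceGraph) -> tuple[np.ndarray, np.ndarray]:
    """Seed mask and the clamped label rows (uniform over a seed's dims)."""
    clamp = np.zeros((graph.n_vertices, graph.n_dims))
    mask = np.zeros(graph.n_vertices, dtype=bool)
    for term, dims in graph.seed_dims.items():
        i = graph.vertex_index[term]
        mask[i] = True
        clamp[i, list(dims)] = 1.0 / len(dims)
    return mask, clamp


def init_labels(graph: CooccurrenceGraph) -> LabelMatrix:
    """Initial labels: seeds one-hot on their dimension, others uniform."""
    if not graph.seed_dims:
        raise ValueError("graph has no seed vertices")
    mask, clamp = _clamped_values(graph)
    values = np.full((graph.n_vertices, graph.n_dims), 1.0 / graph.n_dims)
    values[mask] = clamp[mask]
    return LabelMatrix(graph=graph, values=values, iteration=0)


def propagate(
    graph: CooccurrenceGraph,
    labels: LabelMatrix,
    iterations: int = 10,
    tol: float | None = None,
) -> LabelMatrix:
    """Run synchronous clamped label propagation for ``iterations`` cycles.

    Every cycle replaces each non-seed vertex's label with the
    weight-normalised average of its neighbours' previous-cycle labels;
    seed labels are re-clamped each cycle.  Vertices without (positively
    weighted) neighbours keep their previous label.  When ``tol`` is
    given, iteration stops early once the max-abs change drops below it.
    """
    if labels.graph is not graph:
        raise ValueError("labels were initialized for a different graph")
    mask, clamp = _clamped_values(graph)
    degree = graph.degree()
    active = ~mask & (degree > 0)
    inv_deg = np.zeros_like(degree)
    inv_deg[degree > 0] = 1.0 / degree[degree > 0]

    values = labels.values.copy()
    it = labels.iteration
    for _ in range(iterations):
        new_values = values.copy()
        averaged = graph.weights @ values
        new_values[active] = averaged[active] * inv_deg[active, None]
        new_values[mask] = clamp[mask]
        delta = np.abs(new_values - values).max() if values.size else 0.0
        values = new_values
        it += 1
        if tol is not None and delta < tol:
            break
    return LabelMatrix(graph=graph, values=values, iteration=it)


def fixed_point_oracle(graph: CooccurrenceGraph) -> LabelMatrix:
    """Exact fixed point of the propagation update, by linear solve.

    Non-seed vertices with at least one neighbour satisfy a clamped
    harmonic equation; isolated non-seed vertices stay uniform.  A
    connected component that contains edges but no seed vertex has no
    unique fixed point and raises :class:`SingularSystemError`.
    """
    if not graph.seed_dims:
        raise ValueError("graph has no seed vertices")
    mask, clamp = _clamped_values(graph)
    degree = graph.degree()
    n = graph.n_vertices

    n_comp, comp = connected_components(graph.weights, directed=False)
    seed_comps = set(comp[mask]) if mask.any() else set()
    for c in range(n_comp):
        members = np.nonzero(comp == c)[0]
        if len(members) > 1 and c not in seed_comps:
            names = ", ".join(str(graph.vertices[i]) for i in members[:5])
            raise SingularSystemError(
                f"component without seeds has no unique fixed point: {{{names}"
                + (", ...}" if len(members) > 5 else "}")
            )

    values = np.full((n, graph.n_dims), 1.0 / graph.n_dims)
    values[mask] = clamp[mask]

    free = np.nonzero(~mask & (degree > 0))[0]
    if free.size:
        w = graph.weights.tocsr()
        p = sp.diags(1.0 / degree[free]) @ w[free]
        p_uu = p[:, free]
        fixed = np.nonzero(mask)[0]
        p_us = p[:, fixed]
        rhs = p_us @ values[fixed]
        a = np.eye(free.size) - p_uu.toarray()
        values[free] = np.linalg.solve(a, rhs)
    return LabelMatrix(graph=graph, values=values, iteration=-1)


def _label_cosine(a: np.ndarray, b: np.ndarray) -> float:
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    if denom == 0.0:
        return 0.0
    return float(a @ b) / denom


def rank_lp(
    source_labels: LabelMatrix,
    target_labels: LabelMatrix,
    test_term: TermType,
    include_seeds: bool = True,
    frequencies: dict[TermType, int] | None = None,
) -> CandidateRanking:
    """Rank target vertices by cosine of converged label vectors."""
    if source_labels.graph.n_dims != target_labels.graph.n_dims:
        raise ValueError("label matrices use different dimension spaces")
    if test_term not in source_labels.graph.vertex_index:
        raise KeyError(f"test term not in source graph: {test_term}")
    q = source_labels.label_of(test_term)
    tgraph = target_labels.graph
    scored = []
    for term in tgraph.vertices:
        if not include_seeds and tgraph.is_seed(term):
            continue
        scored.append((term, _label_cosine(q, target_labels.label_of(term))))
    scored.sort(key=candidate_sort_key(frequencies))
    return CandidateRanking(test_term=test_term, candidates=scored)


@dataclass
class LPModel:
    """Bundled source/target label matrices ready for candidate ranking."""

    source_labels: LabelMatrix
    target_labels: LabelMatrix
    target_frequencies: dict[TermType, int] | None = None
    include_seeds: bool = True

    def rank(self, test_term: TermType) -> CandidateRanking:
        return rank_lp(
            self.source_labels,
            self.target_labels,
            test_term,
            include_seeds=self.include_seeds,
            frequencies=self.target_frequencies,
        )

    def has_vertex(self, term: TermType) -> bool:
        return term in self.source_labels.graph.vertex_index


def write_graph_tsv(graph: CooccurrenceGraph, path) -> None:
    """Export the edge list as TSV: term_i, term_j, weight."""
    coo = sp.triu(graph.weights, k=1).tocoo()
    edges = sorted(
        (graph.vertices[i], graph.vertices[j], w)
        for i, j, w in zip(coo.row, coo.col, coo.data)
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_i\tterm_j\tweight\n")
        for a, b, w in edges:
            fh.write(f"{' '.join(a.words)}\t{' '.join(b.words)}\t{w:.10g}\n")


def write_labels_tsv(labels: LabelMatrix, path) -> None:
    """Export labels as TSV: term, dimension, value (nonzero entries)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tdimension\tvalue\n")
        for term in sorted(labels.graph.vertices):
            row = labels.label_of(term)
            for dim in np.nonzero(row)[0]:
                fh.write(f"{' '.join(term.words)}\t{dim}\t{row[dim]:.10g}\n")
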