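"""Seed-indexed context vectors and the context-similarity baseline.

A term's context vector has one dimension per seed translation pair.
The context window is deliberately narrow: for every occurrence of a
term, only the nearest seed occurrence strictly to its left and the
nearest strictly to its right contribute, one count each.  This keeps
the context scope comparable across languages with very different
sentence lengths.  Weights are raw frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from bilex.corpus_io import (
    AnnotatedCorpus,
    SeedLexicon,
    TermType,
    VocabEntry,
)

__all__ = [
    "CandidateRanking",
    "ContextVector",
    "WindowPolicy",
    "candidate_sort_key",
    "cosine",
    "extract_context_vectors",
    "rank_baseline",
]


@dataclass
class ContextVector:
    """Sparse nonnegative weights over seed-pair dimensions."""

    n: int
    weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim, w in self.weights.items():
            if dim < 0 or dim >= self.n:
                raise ValueError(f"dimension {dim} outside [0, {self.n})")
            if w < 0:
                raise ValueError(f"negative weight {w} on dimension {dim}")

    def add(self, dim: int, weight: float = 1.0) -> None:
        if dim < 0 or dim >= self.n:
            raise ValueError(f"dimension {dim} outside [0, {self.n})")
        self.weights[dim] = self.weights.get(dim, 0.0) + weight

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))

    def dot(self, other: "ContextVector") -> float:
        if self.n != other.n:
            raise ValueError(f"dimension mismatch: {self.n} != {other.n}")
        a, b = self.weights, other.weights
        if len(b) < len(a):
            a, b = b, a
        return sum(w * b[d] for d, w in a.items() if d in b)


@dataclass(frozen=True)
class WindowPolicy:
    """Nearest-seed-on-each-side context window.

    ``sentence_bounded`` restricts the search to the occurrence's own
    sentence; ``max_token_distance`` optionally caps how far (in tokens
    from the span boundary) a neighbouring seed may be.
    """

    sentence_bounded: bool = True
    max_token_distance: int | None = None

    def __post_init__(self) -> None:
        if self.max_token_distance is not None and self.max_token_distance < 1:
            raise ValueError("max_token_distance must be >= 1 when set")


@dataclass
class CandidateRanking:
    """Ordered (candidate term, score) list for one test term."""

    test_term: TermType
    candidates: list[tuple[TermType, float]]

    def rank_of(self, term: TermType) -> int | None:
        """1-based rank of ``term``, or None if absent."""
        for i, (cand, _score) in enumerate(self.candidates, start=1):
            if cand == term:
                return i
        return None

    def top(self, k: int) -> list[tuple[TermType, float]]:
        return self.candidates[:k]


def cosine(f_i: ContextVector, f_j: ContextVector) -> float:
    """Cosine similarity in [0, 1]; 0 when either vector is all-zero."""
    denom = f_i.norm * f_j.norm
    if denom == 0.0:
        return 0.0
    return f_i.dot(f_j) / denom


def _flatten_document(doc):
    """Global token offset per sentence so windows may cross sentences."""
    offsets = []
    total = 0
    for sent in doc.sentences:
        offsets.append(total)
        total += len(sent)
    return offsets


def extract_context_vectors(
    corpus: AnnotatedCorpus,
    lexicon: SeedLexicon,
    policy: WindowPolicy = WindowPolicy(),
    side: str | None = None,
) -> dict[TermType, ContextVector]:
    """Build one context vector per vocabulary TermType.

    For each occurrence of each term (seed occurrences included — their
    vectors are needed for edge weights), the nearest seed occurrence
    strictly left and strictly right each add +1 to every dimension that
    seed term participates in.  A side with no seed contributes nothing.
    """
    if lexicon.n == 0:
        raise ValueError("empty seed lexicon")
    if side is None:
        side = lexicon.side_for_language(corpus.language)
    seed_dims = lexicon.dims_by_term(side)

    vectors: dict[TermType, ContextVector] = {}
    n = lexicon.n
    for doc in corpus.documents:
        offsets = _flatten_document(doc)
        # occurrences annotated with global offsets and seed dimensions
        occs = []
        for occ in doc.term_occurrences:
            term = corpus.term_type(doc, occ)
            g_start = offsets[occ.sentence_index] + occ.start
            g_end = offsets[occ.sentence_index] + occ.end
            occs.append((g_start, g_end, occ.sentence_index, term))
        occs.sort(key=lambda t: (t[0], t[1]))
        seed_occs = [o for o in occs if o[3] in seed_dims]

        for g_start, g_end, sent_idx, term in occs:
            vec = vectors.setdefault(term, ContextVector(n))
            # nearest seed strictly to the left
            best_left = None
            best_right = None
            for s_start, s_end, s_sent, s_term in seed_occs:
                if policy.sentence_bounded and s_sent != sent_idx:
                    continue
                if s_end <= g_start:
                    dist = g_start - s_end
                    if best_left is None or dist < best_left[0]:
                        best_left = (dist, s_term)
                elif s_start >= g_end:
                    dist = s_start - g_end
                    if best_right is None or dist < best_right[0]:
                        best_right = (dist, s_term)
            cap = policy.max_token_distance
            for best in (best_left, best_right):
                if best is None:
                    continue
                dist, s_term = best
                if cap is not None and dist > cap:
                    continue
                for dim in seed_dims[s_term]:
                    vec.add(dim)
    return vectors


def candidate_sort_key(frequencies: dict[TermType, int] | None):
    """Deterministic tie-break: higher corpus frequency, then word tuple."""

    def key(item: tuple[TermType, float]):
        term, score = item
        freq = frequencies.get(term, 0) if frequencies else 0
        return (-score, -freq, term.words)

    return key


def rank_baseline(
    test_vector: ContextVector,
    target_vectors: dict[TermType, ContextVector],
    test_term: TermType | None = None,
    frequencies: dict[TermType, int] | None = None,
) -> CandidateRanking:
    """Rank target candidates by cosine with the test term's vector."""
    if not target_vectors:
        raise ValueError("empty candidate set")
    scored = [
        (term, cosine(test_vector, vec)) for term, vec in target_vectors.items()
    ]
    scored.sort(key=candidate_sort_key(frequencies))
    if test_term is None:
        test_term = TermType("?", ("?",))
    return CandidateRanking(test_term=test_term, candidates=scored)


def frequencies_of(vocabulary: dict[TermType, VocabEntry]) -> dict[TermType, int]:
    return {t: e.frequency for t, e in vocabulary.items()}


def write_vectors_tsv(vectors: dict[TermType, ContextVector], path) -> None:
    """Export vectors as TSV: term, dimension, weight (sorted for determinism)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tdimension\tweight\n")
        for term in sorted(vectors):
            vec = vectors[term]
            for dim in sorted(vec.weights):
                fh.write(f"{' '.join(term.words)}\t{dim}\t{vec.weights[dim]:g}\n")


def read_ranking_tsv(
    path, test_language: str, candidate_language: str
) -> dict[TermType, CandidateRanking]:
    """Read rankings written by :func:`write_ranking_tsv`."""
    from bilex.corpus_io import fold_words

    rankings: dict[TermType, CandidateRanking] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["test_term", "rank", "candidate", "score"]:
            raise ValueError(f"unexpected ranking header: {header}")
        for line in fh:
            test_col, _rank, cand_col, score = line.rstrip("\n").split("\t")
            test = TermType(test_language, fold_words(test_col.split()))
            cand = TermType(candidate_language, fold_words(cand_col.split()))
            rankings.setdefault(
                test, CandidateRanking(test_term=test, candidates=[])
            ).candidates.append((cand, float(score)))
    return rankings


def write_ranking_tsv(rankings: list[CandidateRanking], path, top: int = 100) -> None:
    """Export rankings as TSV: test_term, rank, candidate, score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("test_term\trank\tcandidate\tscore\n")
        for ranking in rankings:
            for rank, (cand, score) in enumerate(ranking.top(top), start=1):
                fh.write(
                    f"{' '.join(ranking.test_term.words)}\t{rank}\t"
                    f"{' '.join(cand.words)}\t{score:.10g}\n"
                )
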