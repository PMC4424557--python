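"""Multi-word-term alignment by component-wise candidate combination.

A source multi-word term rarely has a translation that can be ranked
directly: its corpus frequency is too low for reliable context.  Its
component words, however, are frequent.  The alignment therefore
(1) ranks target candidates for every component word, (2) intersects
the flattened candidate word sets, (3) matches word subsets of the
intersection against terms that actually occur in the target corpus,
and (4) ranks the matched terms by the average component-to-word
similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

from bilex.context import CandidateRanking
from bilex.corpus_io import TermType, TermWordIndex
from bilex.lp import LPModel

__all__ = [
    "CandidateCombination",
    "MWTQuery",
    "align_mwt",
    "component_candidate_words",
    "enumerate_combinations",
    "examined_subset_count",
    "intersect_candidates",
    "ordered_subset_count",
    "score_combination",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MWTQuery:
    """A source multi-word term and its single-word component vertices."""

    term: TermType
    components: tuple[TermType, ...]

    def __post_init__(self) -> None:
        if len(self.term.words) < 2:
            raise ValueError(f"not a multi-word term: {self.term}")
        if tuple(c.words[0] for c in self.components) != self.term.words:
            raise ValueError("components must be the term's words, in order")

    @classmethod
    def from_term(cls, term: TermType) -> "MWTQuery":
        return cls(
            term=term,
            components=tuple(TermType(term.language, (w,)) for w in term.words),
        )


@dataclass
class CandidateCombination:
    """A surviving word subset with the target terms it matched."""

    words: frozenset[str]
    matched: list[TermType]
    score: float | None = None


def component_candidate_words(
    component: TermType, lp_model: LPModel, K: int = 100
) -> dict[str, float]:
    """Step 1: top-K target terms for one component, flattened to words.

    Each word's similarity is the best ranking score among the top-K
    terms containing it.  Returned in descending-similarity order.
    """
    if not lp_model.has_vertex(component):
        raise KeyError(f"component not in source graph: {component}")
    if K <= 0:
        return {}
    ranking = lp_model.rank(component)
    sims: dict[str, float] = {}
    for term, score in ranking.top(K):
        for word in term.words:
            if score > sims.get(word, -1.0):
                sims[word] = score
    return dict(sorted(sims.items(), key=lambda kv: (-kv[1], kv[0])))


def intersect_candidates(
    candidate_word_sets: list[dict[str, float]],
) -> dict[str, tuple[float, ...]]:
    """Step 2: words present in every component's candidate set.

    Each surviving word keeps its per-component similarities (in
    component order).
    """
    if len(candidate_word_sets) < 2:
        raise ValueError("need candidate sets for at least 2 components")
    common = set(candidate_word_sets[0])
    for s in candidate_word_sets[1:]:
        common &= set(s)
    return {
        w: tuple(s[w] for s in candidate_word_sets) for w in sorted(common)
    }


def examined_subset_count(q: int, n_max: int) -> int:
    """Number of unordered subsets of sizes 1..n_max from q words."""
    return sum(comb(q, j) for j in range(1, min(q, n_max) + 1))


def ordered_subset_count(q: int, n_max: int) -> int:
    """Ordered-tuple workload estimate (q - q^n) / (1 - q); diagnostic only."""
    if q <= 1:
        return q * n_max
    return (q ** n_max - q) // (q - 1)


def enumerate_combinations(
    intersection: dict[str, tuple[float, ...]] | set[str] | list[str],
    n_max: int,
    index: TermWordIndex,
) -> list[CandidateCombination]:
    """Step 3: keep word subsets that match at least one target term.

    All unordered subsets of sizes 1..n_max are tried against the target
    term-word index; a subset survives iff some target term's word set
    equals it exactly.
    """
    words = sorted(intersection)
    q = len(words)
    survivors: list[CandidateCombination] = []
    examined = 0
    for j in range(1, min(q, max(n_max, 0)) + 1):
        for subset in combinations(words, j):
            examined += 1
            key = frozenset(subset)
            matched = index.get(key)
            if matched:
                survivors.append(
                    CandidateCombination(words=key, matched=list(matched))
                )
    logger.debug(
        "subset enumeration: q=%d n_max=%d examined=%d (ordered estimate %d), "
        "survivors=%d",
        q,
        n_max,
        examined,
        ordered_subset_count(q, n_max) if q else 0,
        len(survivors),
    )
    return survivors


def score_combination(
    combination: CandidateCombination,
    component_sims: list[dict[str, float]],
    mode: str = "pairs-mean",
) -> float:
    """Step 4 plausibility: average component-word similarity.

    ``pairs-mean`` (default) averages sim(component, word) over all
    (component, candidate word) pairs, counting 0 for a word absent from
    a component's candidate set.  ``best-match`` averages, over
    components, each component's best similarity to any candidate word.
    """
    if not combination.words:
        raise ValueError("empty combination")
    if not component_sims:
        raise ValueError("no component similarities")
    words = sorted(combination.words)
    if mode == "pairs-mean":
        total = sum(sims.get(w, 0.0) for sims in component_sims for w in words)
        return total / (len(component_sims) * len(words))
    if mode == "best-match":
        total = sum(
            max(sims.get(w, 0.0) for w in words) for sims in component_sims
        )
        return total / len(component_sims)
    raise ValueError(f"unknown scoring mode {mode!r}")


def align_mwt(
    query: MWTQuery,
    lp_model: LPModel,
    index: TermWordIndex,
    K: int = 100,
    n_max: int | None = None,
    score_mode: str = "pairs-mean",
    allow_partial: bool = False,
) -> CandidateRanking:
    """Steps 1-4: rank target-term translation candidates for one MWT.

    ``n_max`` bounds the candidate translation length; it defaults to the
    number of source words (translations longer than the source term are
    out of reach by design).  With ``allow_partial``, components missing
    from the source graph are skipped as long as at least two remain.
    """
    components = list(query.components)
    missing = [c for c in components if not lp_model.has_vertex(c)]
    if missing:
        if not allow_partial or len(components) - len(missing) < 2:
            raise KeyError(
                "components missing from source graph: "
                + ", ".join(str(c) for c in missing)
            )
        logger.warning(
            "aligning %s without %d missing component(s): %s",
            query.term,
            len(missing),
            ", ".join(str(c) for c in missing),
        )
        components = [c for c in components if c not in missing]

    if n_max is None:
        n_max = len(query.term.words)

    sims_per_component = [
        component_candidate_words(c, lp_model, K) for c in components
    ]
    intersection = intersect_candidates(sims_per_component)
    survivors = enumerate_combinations(intersection, n_max, index)

    best: dict[TermType, float] = {}
    for combo in survivors:
        combo.score = score_combination(combo, sims_per_component, mode=score_mode)
        for term in combo.matched:
            if combo.score > best.get(term, -1.0):
                best[term] = combo.score
    ranked = sorted(
        best.items(), key=lambda kv: (-kv[1], len(kv[0].words), kv[0].words)
    )
    return CandidateRanking(test_term=query.term, candidates=ranked)
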