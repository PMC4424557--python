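"""Synthetic comparable-corpus generator with a planted bilingual lexicon.

The generator emulates the data regime the extraction pipeline is built
for: two monolingual corpora about the same domain, a scarce seed
lexicon, language-asymmetric sentence lengths, and m-to-n multi-word
translation pairs.  Every planted translation pair draws one sparse
"affinity" distribution over seed-pair dimensions, shared across the two
languages; each occurrence of a planted term is placed flanked by seed
terms drawn from that distribution (with per-language uniform noise at
rate epsilon).  At epsilon = 0 the two sides of a single-word pair see
byte-identical flanker sequences, so their context vectors are exact
mirrors.

Multi-word pairs place their m component words as one contiguous
annotated source term and an n-word annotated target term.  Component
words additionally occur standalone with the pair's affinity (they are
frequent and reliable), while the whole source MWT occurs only a few
times with (by default) uniformly random flankers — its direct context
is unreliable, which is precisely the failure mode the alignment
procedure addresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bilex.corpus_io import (
    AnnotatedCorpus,
    Document,
    SeedLexicon,
    TermOccurrence,
    TermType,
)
from bilex.evaluation import GoldLexicon

__all__ = [
    "TABLE_MWT_COUNTS",
    "SynthConfig",
    "SynthOutput",
    "generate_comparable_corpora",
]

#: Observed length distribution of m-to-n multi-word translation pairs,
#: usable as a realistic default shape for ``mwt_pair_counts``.
TABLE_MWT_COUNTS: dict[tuple[int, int], int] = {
    (2, 1): 11,
    (2, 2): 14,
    (3, 2): 2,
    (3, 3): 1,
    (1, 2): 7,
    (2, 3): 2,
}


#: Symmetric Dirichlet concentration for per-pair affinity weights.  Kept
#: well above 1 so no preferred dimension starves: a starved dimension
#: collapses a pair's context to a single seed, which is indistinguishable
#: from that seed itself.
_DIRICHLET_CONCENTRATION = 8.0

#: Probability mass a seed term's affinity puts on its own dimension.
_SEED_SELF_AFFINITY = 0.6


class InfeasibleConfigError(ValueError):
    """The configuration cannot produce a valid corpus pair."""


@dataclass
class SynthConfig:
    """Generator configuration.

    ``sentences_per_doc``, ``terms_per_sentence`` and ``noise_rate`` are
    (source, target) pairs; source sentences hold more terms by default,
    emulating the much longer source-language sentences.  When
    ``occurrences_per_pair`` is None it is derived from the corpus
    capacity implied by the document/sentence counts.
    """

    n_seed_pairs: int = 50
    n_swt_pairs: int = 30
    mwt_pair_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    docs_per_language: int = 10
    sentences_per_doc: tuple[int, int] = (30, 45)
    terms_per_sentence: tuple[int, int] = (3, 2)
    affinity_sparsity: int = 2
    noise_rate: tuple[float, float] = (0.0, 0.0)
    rng_seed: int = 0
    occurrences_per_pair: int | None = None
    #: occurrences for planted single-word test pairs; defaults to
    #: occurrences_per_pair (test terms are rarer than seeds in practice)
    swt_occurrences: int | None = None
    mwt_term_occurrences: int = 4
    mwt_source_context_noise: float = 1.0
    source_language: str = "zh"
    target_language: str = "en"

    def validate(self) -> None:
        if self.n_seed_pairs < 0 or self.n_swt_pairs < 0:
            raise InfeasibleConfigError("negative pair counts")
        if any(c < 0 for c in self.mwt_pair_counts.values()):
            raise InfeasibleConfigError("negative MWT pair count")
        for eps in self.noise_rate:
            if not 0.0 <= eps <= 1.0:
                raise InfeasibleConfigError(f"noise rate {eps} outside [0, 1]")
        if not 0.0 <= self.mwt_source_context_noise <= 1.0:
            raise InfeasibleConfigError("mwt_source_context_noise outside [0, 1]")
        planted = self.n_swt_pairs + sum(self.mwt_pair_counts.values())
        if planted and self.affinity_sparsity > self.n_seed_pairs:
            raise InfeasibleConfigError(
                f"affinity_sparsity {self.affinity_sparsity} exceeds "
                f"n_seed_pairs {self.n_seed_pairs}"
            )
        if planted and self.affinity_sparsity < 1:
            raise InfeasibleConfigError("affinity_sparsity must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        data = dict(data)
        if "mwt_pair_counts" in data:
            counts = {}
            for key, value in data["mwt_pair_counts"].items():
                if isinstance(key, str):
                    m, n = key.replace("-", " ").replace("to", " ").split()
                    key = (int(m), int(n))
                counts[tuple(key)] = int(value)
            data["mwt_pair_counts"] = counts
        for f in ("sentences_per_doc", "terms_per_sentence", "noise_rate"):
            if f in data:
                data[f] = tuple(data[f])
        return cls(**data)


@dataclass
class SynthOutput:
    """The generated corpora plus all planted lexicons."""

    source_corpus: AnnotatedCorpus
    target_corpus: AnnotatedCorpus
    seed_lexicon: SeedLexicon
    gold_swt: GoldLexicon
    gold_mwt: GoldLexicon
    #: per planted pair: affinity support dims (diagnostics / tests)
    affinities: dict[TermType, tuple[int, ...]] = field(default_factory=dict)


@dataclass
class _Pair:
    """One planted translation pair and its affinity distribution."""

    name: str
    source_term: TermType
    target_term: TermType
    support: np.ndarray
    probs: np.ndarray
    kind: str  # "swt" | "mwt"


def _draw_support(
    rng: np.random.Generator, n_dims: int, k: int, used: set[tuple[int, ...]]
) -> np.ndarray:
    """A k-subset of dimensions not used by any other planted pair."""
    for _ in range(1000):
        support = tuple(sorted(rng.choice(n_dims, size=k, replace=False).tolist()))
        if support not in used:
            used.add(support)
            return np.array(support)
    raise InfeasibleConfigError(
        f"cannot find {k}-dim affinity supports distinct across planted pairs "
        f"(n_seed_pairs={n_dims} too small)"
    )


def _flanker_stream(
    rng: np.random.Generator, pair: _Pair, count: int
) -> list[tuple[int, int]]:
    """(left dim, right dim) per occurrence, drawn from the pair's affinity."""
    if count == 0:
        return []
    draws = rng.choice(pair.support, size=(count, 2), p=pair.probs)
    return [tuple(map(int, row)) for row in draws]


def _uniform_stream(
    rng: np.random.Generator, n_dims: int, count: int
) -> list[tuple[int, int]]:
    draws = rng.integers(0, n_dims, size=(count, 2))
    return [tuple(map(int, row)) for row in draws]


@dataclass
class _Event:
    """One centered term occurrence awaiting placement in a sentence."""

    words: tuple[str, ...]
    flank: tuple[int, int]
    annotate_span: bool = True


def _apply_noise(
    events: list[_Event], eps: float, n_dims: int, rng: np.random.Generator
) -> None:
    if eps <= 0.0:
        return
    for ev in events:
        left, right = ev.flank
        if rng.random() < eps:
            left = int(rng.integers(0, n_dims))
        if rng.random() < eps:
            right = int(rng.integers(0, n_dims))
        ev.flank = (left, right)


def _pack_documents(
    events: list[_Event],
    seed_words: list[str],
    language: str,
    terms_per_sentence: int,
    sentences_per_doc: int,
) -> AnnotatedCorpus:
    """Lay events out as [seed, term..., seed] triples packed into sentences."""
    documents: list[Document] = []
    sentences: list[list[str]] = []
    occurrences: list[TermOccurrence] = []

    def flush_doc() -> None:
        nonlocal sentences, occurrences
        if sentences:
            documents.append(
                Document(
                    doc_id=f"{language}{len(documents):04d}",
                    sentences=sentences,
                    term_occurrences=occurrences,
                )
            )
            sentences, occurrences = [], []

    for i in range(0, len(events), terms_per_sentence):
        chunk = events[i : i + terms_per_sentence]
        tokens: list[str] = []
        sent_index = len(sentences)
        for ev in chunk:
            left_dim, right_dim = ev.flank
            pos = len(tokens)
            tokens.append(seed_words[left_dim])
            occurrences.append(
                TermOccurrence(sent_index, pos, pos + 1, "treatment")
            )
            start = len(tokens)
            tokens.extend(ev.words)
            if ev.annotate_span:
                occurrences.append(
                    TermOccurrence(sent_index, start, start + len(ev.words), "problem")
                )
            pos = len(tokens)
            tokens.append(seed_words[right_dim])
            occurrences.append(
                TermOccurrence(sent_index, pos, pos + 1, "treatment")
            )
        sentences.append(tokens)
        if len(sentences) >= sentences_per_doc:
            flush_doc()
    flush_doc()
    return AnnotatedCorpus(language=language, documents=documents)


def generate_comparable_corpora(config: SynthConfig) -> SynthOutput:
    """Generate a source/target corpus pair with planted translations.

    Deterministic: identical configs (including ``rng_seed``) produce
    byte-identical corpora.
    """
    config.validate()
    n_dims = config.n_seed_pairs
    src_lang, tgt_lang = config.source_language, config.target_language

    seed_pairs = [
        (
            TermType(src_lang, (f"cs{i:03d}",)),
            TermType(tgt_lang, (f"es{i:03d}",)),
        )
        for i in range(n_dims)
    ]
    lexicon = SeedLexicon(pairs=seed_pairs)
    src_seed_words = [p[0].words[0] for p in seed_pairs]
    tgt_seed_words = [p[1].words[0] for p in seed_pairs]

    # --- planted pairs -----------------------------------------------------
    used_supports: set[tuple[int, ...]] = set()
    support_rng = np.random.default_rng([config.rng_seed, 101])

    # Seed terms are domain terms too: each seed pair occurs centered in
    # sentences, not only as a flanker, with an affinity dominated by its
    # OWN dimension.  A seed's context vector is then a sharp signature of
    # its dimension, so cosine edge weights separate genuinely related
    # co-occurrences from incidental same-sentence ones, and hidden seeds
    # act as informative intermediate vertices for label propagation.
    seed_affinities: list[_Pair] = []
    if n_dims > config.affinity_sparsity:
        for i in range(n_dims):
            for _ in range(1000):
                others = tuple(
                    sorted(
                        d
                        for d in support_rng.choice(
                            n_dims, size=config.affinity_sparsity, replace=False
                        ).tolist()
                        if d != i
                    )
                )
                if others and (i,) + others not in used_supports:
                    used_supports.add((i,) + others)
                    break
            else:  # pragma: no cover - needs pathological configs
                raise InfeasibleConfigError(
                    "cannot draw distinct seed affinity supports"
                )
            other_probs = np.random.default_rng([config.rng_seed, 110, i]).dirichlet(
                np.full(len(others), _DIRICHLET_CONCENTRATION)
            )
            probs = np.concatenate(
                [[_SEED_SELF_AFFINITY], (1.0 - _SEED_SELF_AFFINITY) * other_probs]
            )
            seed_affinities.append(
                _Pair(
                    name=f"seed{i}",
                    source_term=seed_pairs[i][0],
                    target_term=seed_pairs[i][1],
                    support=np.array((i,) + others),
                    probs=probs,
                    kind="seed",
                )
            )

    swt_pairs: list[_Pair] = []
    for i in range(config.n_swt_pairs):
        support = _draw_support(
            support_rng, n_dims, config.affinity_sparsity, used_supports
        )
        probs = np.random.default_rng([config.rng_seed, 102, i]).dirichlet(
            np.full(len(support), _DIRICHLET_CONCENTRATION)
        )
        swt_pairs.append(
            _Pair(
                name=f"swt{i}",
                source_term=TermType(src_lang, (f"cw{i:03d}",)),
                target_term=TermType(tgt_lang, (f"ew{i:03d}",)),
                support=support,
                probs=probs,
                kind="swt",
            )
        )

    mwt_pairs: list[_Pair] = []
    p_idx = 0
    for (m, n), count in sorted(config.mwt_pair_counts.items()):
        if m < 1 or n < 1:
            raise InfeasibleConfigError(f"invalid m-to-n shape ({m}, {n})")
        for _ in range(count):
            support = _draw_support(
                support_rng, n_dims, config.affinity_sparsity, used_supports
            )
            probs = np.random.default_rng(
                [config.rng_seed, 103, p_idx]
            ).dirichlet(np.full(len(support), _DIRICHLET_CONCENTRATION))
            mwt_pairs.append(
                _Pair(
                    name=f"mwt{p_idx}",
                    source_term=TermType(
                        src_lang, tuple(f"cm{p_idx:03d}x{j}" for j in range(m))
                    ),
                    target_term=TermType(
                        tgt_lang, tuple(f"em{p_idx:03d}x{j}" for j in range(n))
                    ),
                    support=support,
                    probs=probs,
                    kind="mwt",
                )
            )
            p_idx += 1

    # --- occurrence budget -------------------------------------------------
    n_components = sum(len(p.source_term.words) for p in mwt_pairs)
    src_units = config.n_swt_pairs + n_components + len(seed_affinities)
    tgt_units = config.n_swt_pairs + len(mwt_pairs) + len(seed_affinities)
    occ = config.occurrences_per_pair
    if occ is None:
        cap_src = (
            config.docs_per_language
            * config.sentences_per_doc[0]
            * config.terms_per_sentence[0]
        )
        cap_tgt = (
            config.docs_per_language
            * config.sentences_per_doc[1]
            * config.terms_per_sentence[1]
        )
        cap_src -= config.mwt_term_occurrences * len(mwt_pairs)
        budgets = []
        if src_units:
            budgets.append(cap_src // src_units)
        if tgt_units:
            budgets.append(cap_tgt // tgt_units)
        occ = min(budgets) if budgets else 0
    if (src_units or tgt_units) and occ < 1:
        raise InfeasibleConfigError(
            "corpus capacity too small for at least one occurrence per planted term"
        )

    # --- events ------------------------------------------------------------
    src_events: list[_Event] = []
    tgt_events: list[_Event] = []

    swt_occ = config.swt_occurrences if config.swt_occurrences is not None else occ

    # Flanker dims are drawn independently per language from the SHARED
    # per-pair affinity distribution: the two sides see samples of the
    # same context distribution, not copies of one sample.
    for i, pair in enumerate(seed_affinities):
        for side, events in ((0, src_events), (1, tgt_events)):
            stream = _flanker_stream(
                np.random.default_rng([config.rng_seed, 111, i, side]), pair, occ
            )
            term = pair.source_term if side == 0 else pair.target_term
            for flank in stream:
                events.append(_Event(term.words, flank))

    for i, pair in enumerate(swt_pairs):
        for side, events in ((0, src_events), (1, tgt_events)):
            stream = _flanker_stream(
                np.random.default_rng([config.rng_seed, 104, i, side]),
                pair,
                swt_occ,
            )
            term = pair.source_term if side == 0 else pair.target_term
            for flank in stream:
                events.append(_Event(term.words, flank))

    for p, pair in enumerate(mwt_pairs):
        m = len(pair.source_term.words)
        for j in range(m):
            comp_stream = _flanker_stream(
                np.random.default_rng([config.rng_seed, 105, p, j]), pair, occ
            )
            word = pair.source_term.words[j]
            for flank in comp_stream:
                src_events.append(_Event((word,), flank))
        tgt_stream = _flanker_stream(
            np.random.default_rng([config.rng_seed, 106, p]), pair, occ
        )
        for flank in tgt_stream:
            tgt_events.append(_Event(pair.target_term.words, flank))
        # whole source MWT: few occurrences, mostly uninformative context
        mwt_rng = np.random.default_rng([config.rng_seed, 107, p])
        affinity_stream = _flanker_stream(mwt_rng, pair, config.mwt_term_occurrences)
        noise_stream = _uniform_stream(mwt_rng, n_dims, config.mwt_term_occurrences)
        for k in range(config.mwt_term_occurrences):
            use_noise = mwt_rng.random() < config.mwt_source_context_noise
            flank = noise_stream[k] if use_noise else affinity_stream[k]
            src_events.append(_Event(pair.source_term.words, flank))

    # per-language shuffling and noise
    src_rng = np.random.default_rng([config.rng_seed, 108])
    tgt_rng = np.random.default_rng([config.rng_seed, 109])
    src_order = src_rng.permutation(len(src_events))
    tgt_order = tgt_rng.permutation(len(tgt_events))
    src_events = [src_events[i] for i in src_order]
    tgt_events = [tgt_events[i] for i in tgt_order]
    _apply_noise(src_events, config.noise_rate[0], n_dims, src_rng)
    _apply_noise(tgt_events, config.noise_rate[1], n_dims, tgt_rng)

    source_corpus = _pack_documents(
        src_events,
        src_seed_words,
        src_lang,
        config.terms_per_sentence[0],
        config.sentences_per_doc[0],
    )
    target_corpus = _pack_documents(
        tgt_events,
        tgt_seed_words,
        tgt_lang,
        config.terms_per_sentence[1],
        config.sentences_per_doc[1],
    )
    source_corpus.validate()
    target_corpus.validate()

    gold_swt: GoldLexicon = {
        p.source_term: {p.target_term} for p in swt_pairs
    }
    gold_mwt: GoldLexicon = {
        p.source_term: {p.target_term} for p in mwt_pairs
    }
    affinities = {
        p.source_term: tuple(int(d) for d in p.support)
        for p in swt_pairs + mwt_pairs
    }
    return SynthOutput(
        source_corpus=source_corpus,
        target_corpus=target_corpus,
        seed_lexicon=lexicon,
        gold_swt=gold_swt,
        gold_mwt=gold_mwt,
        affinities=affinities,
    )
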