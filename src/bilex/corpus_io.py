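"""I/O and indexing for annotated corpora and term lexicons.

Corpora are stored as JSON lines, one document per line::

    {"doc_id": str, "lang": str, "sentences": [[token, ...], ...],
     "terms": [{"sent": int, "start": int, "end": int, "cat": str}, ...]}

Term spans are 0-based, half-open token offsets within a sentence.
Lexicons (seed and gold) are two-column TSV files with space-separated
words inside each column; ``#`` starts a comment line.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "CATEGORIES",
    "AnnotatedCorpus",
    "CorpusFormatError",
    "Document",
    "LexiconFormatError",
    "SeedLexicon",
    "TermOccurrence",
    "TermType",
    "TermWordIndex",
    "VocabEntry",
    "build_vocabulary",
    "build_word_index",
    "explode_mwt_components",
    "read_corpus",
    "read_gold_lexicon",
    "read_seed_lexicon",
    "write_corpus",
    "write_lexicon",
]

#: Recognised term categories; anything else is mapped to "other" with a warning.
CATEGORIES = ("problem", "treatment", "test", "other")


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the documented JSONL dialect."""


class LexiconFormatError(ValueError):
    """Raised when a lexicon TSV violates its format contract."""


@dataclass(frozen=True, order=True)
class TermType:
    """Canonical identity of a term: language plus case-folded word tuple."""

    language: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("TermType requires at least one word")

    @property
    def is_mwt(self) -> bool:
        return len(self.words) > 1

    @property
    def word_set(self) -> frozenset[str]:
        return frozenset(self.words)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return " ".join(self.words)


def fold_words(words: Iterable[str]) -> tuple[str, ...]:
    """Case-fold surface words to their canonical form (simple lowercase)."""
    return tuple(w.lower() for w in words)


@dataclass(frozen=True)
class TermOccurrence:
    """A single annotated term span inside one sentence."""

    sentence_index: int
    start: int
    end: int
    category: str = "other"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def is_mwt(self) -> bool:
        return self.end - self.start > 1


@dataclass
class Document:
    doc_id: str
    sentences: list[list[str]]
    term_occurrences: list[TermOccurrence] = field(default_factory=list)

    def validate(self) -> None:
        for occ in self.term_occurrences:
            if occ.sentence_index < 0 or occ.sentence_index >= len(self.sentences):
                raise CorpusFormatError(
                    f"document {self.doc_id!r}: sentence index "
                    f"{occ.sentence_index} out of range"
                )
            sent_len = len(self.sentences[occ.sentence_index])
            if occ.end > sent_len:
                raise CorpusFormatError(
                    f"document {self.doc_id!r}, sentence {occ.sentence_index}: "
                    f"span [{occ.start}, {occ.end}) exceeds sentence length {sent_len}"
                )

    def term_words(self, occ: TermOccurrence) -> tuple[str, ...]:
        return fold_words(self.sentences[occ.sentence_index][occ.start : occ.end])


@dataclass
class AnnotatedCorpus:
    language: str
    documents: list[Document] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusFormatError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            doc.validate()

    def term_type(self, doc: Document, occ: TermOccurrence) -> TermType:
        return TermType(self.language, doc.term_words(occ))

    def iter_occurrences(self):
        """Yield (document, occurrence, TermType) triples in corpus order."""
        for doc in self.documents:
            for occ in doc.term_occurrences:
                yield doc, occ, self.term_type(doc, occ)


@dataclass
class SeedLexicon:
    """Ordered translation pairs; position = context-vector dimension."""

    pairs: list[tuple[TermType, TermType]]

    def __post_init__(self) -> None:
        seen: set[tuple[TermType, TermType]] = set()
        for pair in self.pairs:
            if pair in seen:
                raise LexiconFormatError(
                    f"duplicate seed pair: {pair[0]} / {pair[1]}"
                )
            seen.add(pair)

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def source_language(self) -> str:
        return self.pairs[0][0].language if self.pairs else ""

    @property
    def target_language(self) -> str:
        return self.pairs[0][1].language if self.pairs else ""

    def dims_by_term(self, side: str) -> dict[TermType, tuple[int, ...]]:
        """Map a seed TermType to every dimension it participates in.

        ``side`` is "source" or "target".  One surface term may occur in
        several pairs; it then owns several dimensions.
        """
        idx = 0 if side == "source" else 1
        out: dict[TermType, list[int]] = {}
        for dim, pair in enumerate(self.pairs):
            out.setdefault(pair[idx], []).append(dim)
        return {t: tuple(dims) for t, dims in out.items()}

    def side_for_language(self, language: str) -> str:
        """Which side of the lexicon matches ``language`` ("source"/"target")."""
        if not self.pairs:
            raise LexiconFormatError("empty seed lexicon")
        src, tgt = self.source_language, self.target_language
        if src == tgt:
            raise LexiconFormatError(
                "seed lexicon has identical languages on both sides; "
                "pass side explicitly"
            )
        if language == src:
            return "source"
        if language == tgt:
            return "target"
        raise LexiconFormatError(
            f"language {language!r} matches neither lexicon side ({src}/{tgt})"
        )


@dataclass
class VocabEntry:
    term: TermType
    occurrences: list[tuple[int, TermOccurrence]] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.occurrences)


#: word set -> target terms whose word set equals the key
TermWordIndex = dict[frozenset[str], list[TermType]]


# ---------------------------------------------------------------------------
# corpus reading / writing


def _parse_document(record: dict, line_no: int) -> Document:
    try:
        doc_id = record["doc_id"]
        sentences = [list(map(str, s)) for s in record["sentences"]]
        raw_terms = record.get("terms", [])
    except (KeyError, TypeError) as exc:
        raise CorpusFormatError(f"line {line_no}: malformed document record: {exc}")
    occurrences = []
    for t in raw_terms:
        cat = t.get("cat", "other")
        if cat not in CATEGORIES:
            warnings.warn(
                f"line {line_no}: unknown category {cat!r}; mapped to 'other'",
                stacklevel=3,
            )
            cat = "other"
        try:
            occ = TermOccurrence(
                sentence_index=int(t["sent"]),
                start=int(t["start"]),
                end=int(t["end"]),
                category=cat,
            )
        except (KeyError, ValueError) as exc:
            raise CorpusFormatError(
                f"line {line_no}, document {doc_id!r}: bad term record: {exc}"
            )
        occurrences.append(occ)
    return Document(doc_id=doc_id, sentences=sentences, term_occurrences=occurrences)


def read_corpus(path: str | Path, language: str | None = None) -> AnnotatedCorpus:
    """Read a JSONL corpus file.

    ``language`` overrides / checks the per-document ``lang`` field; if
    omitted, the language is taken from the first document.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    documents: list[Document] = []
    lang = language
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {line_no}: invalid JSON: {exc}")
            if lang is None:
                lang = record.get("lang")
            documents.append(_parse_document(record, line_no))
    corpus = AnnotatedCorpus(language=lang or "", documents=documents)
    corpus.validate()
    return corpus


def write_corpus(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Write a corpus in the canonical JSONL dialect (UTF-8, sorted keys)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            record = {
                "doc_id": doc.doc_id,
                "lang": corpus.language,
                "sentences": doc.sentences,
                "terms": [
                    {
                        "sent": o.sentence_index,
                        "start": o.start,
                        "end": o.end,
                        "cat": o.category,
                    }
                    for o in doc.term_occurrences
                ],
            }
            fh.write(json.dumps(record, ensure_ascii=False, sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# lexicon reading / writing


def _iter_lexicon_lines(path: Path):
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                warnings.warn(f"{path.name}:{line_no}: blank line skipped", stacklevel=4)
                continue
            if stripped.lstrip().startswith("#"):
                continue
            cols = stripped.split("\t")
            if len(cols) != 2:
                raise LexiconFormatError(
                    f"{path.name}:{line_no}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            yield line_no, cols[0], cols[1]


def _header_like(a: str, b: str) -> bool:
    return {a.strip().lower(), b.strip().lower()} == {"source_term", "target_term"}


def read_seed_lexicon(
    path: str | Path,
    source_language: str = "zh",
    target_language: str = "en",
) -> SeedLexicon:
    """Read a seed lexicon TSV; line order defines dimension order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"seed lexicon not found: {path}")
    pairs: list[tuple[TermType, TermType]] = []
    for line_no, src_col, tgt_col in _iter_lexicon_lines(path):
        if not pairs and _header_like(src_col, tgt_col):
            continue
        src = TermType(source_language, fold_words(src_col.split()))
        tgt = TermType(target_language, fold_words(tgt_col.split()))
        pairs.append((src, tgt))
    return SeedLexicon(pairs=pairs)


def read_gold_lexicon(
    path: str | Path,
    source_language: str = "zh",
    target_language: str = "en",
) -> dict[TermType, set[TermType]]:
    """Read a gold lexicon TSV as source term -> set of acceptable targets."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gold lexicon not found: {path}")
    gold: dict[TermType, set[TermType]] = {}
    first = True
    for line_no, src_col, tgt_col in _iter_lexicon_lines(path):
        if first and _header_like(src_col, tgt_col):
            first = False
            continue
        first = False
        src = TermType(source_language, fold_words(src_col.split()))
        tgt = TermType(target_language, fold_words(tgt_col.split()))
        gold.setdefault(src, set()).add(tgt)
    return gold


def write_lexicon(
    pairs: Iterable[tuple[TermType, TermType]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for src, tgt in pairs:
            fh.write(f"{' '.join(src.words)}\t{' '.join(tgt.words)}\n")


# ---------------------------------------------------------------------------
# vocabulary / index construction


def build_vocabulary(corpus: AnnotatedCorpus) -> dict[TermType, VocabEntry]:
    """Group every term occurrence under its case-folded TermType."""
    vocab: dict[TermType, VocabEntry] = {}
    for doc_index, doc in enumerate(corpus.documents):
        for occ in doc.term_occurrences:
            term = corpus.term_type(doc, occ)
            vocab.setdefault(term, VocabEntry(term)).occurrences.append(
                (doc_index, occ)
            )
    return vocab


def explode_mwt_components(corpus: AnnotatedCorpus) -> AnnotatedCorpus:
    """Return a corpus with each multi-word occurrence also annotated per word.

    Every occurrence spanning more than one token gains one extra
    single-token occurrence per component word (same category), so that
    component words become first-class vocabulary terms and graph
    vertices.  The input corpus is not modified.
    """
    new_docs = []
    for doc in corpus.documents:
        extra = []
        for occ in doc.term_occurrences:
            if occ.is_mwt:
                for pos in range(occ.start, occ.end):
                    extra.append(
                        TermOccurrence(
                            sentence_index=occ.sentence_index,
                            start=pos,
                            end=pos + 1,
                            category=occ.category,
                        )
                    )
        new_docs.append(
            Document(
                doc_id=doc.doc_id,
                sentences=doc.sentences,
                term_occurrences=list(doc.term_occurrences) + extra,
            )
        )
    return AnnotatedCorpus(language=corpus.language, documents=new_docs)


def build_word_index(vocabulary: dict[TermType, VocabEntry]) -> TermWordIndex:
    """Index target-language terms by their (order-insensitive) word set.

    Duplicated words within one term collapse: lookup is by set
    equality, not multiset equality.
    """
    index: TermWordIndex = {}
    for term in vocabulary:
        index.setdefault(term.word_set, []).append(term)
    for terms in index.values():
        terms.sort()
    return index
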