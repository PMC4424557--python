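"""Shared fixtures: tiny hand-built corpora and lexicons."""

from __future__ import annotations

import pytest

from bilex.corpus_io import (
    AnnotatedCorpus,
    Document,
    SeedLexicon,
    TermOccurrence,
    TermType,
)


def make_document(doc_id, sentences, spans):
    """Build a Document from token sentences and (sent, start, end[, cat]) spans."""
    occs = [
        TermOccurrence(*span) if len(span) == 4 else TermOccurrence(*span, "problem")
        for span in spans
    ]
    return Document(doc_id=doc_id, sentences=sentences, term_occurrences=occs)


def make_corpus(language, docs):
    corpus = AnnotatedCorpus(language=language, documents=docs)
    corpus.validate()
    return corpus


def annotate_all_tokens(language, doc_id, sentences):
    """Corpus where every single token is an annotated term."""
    spans = [
        (i, j, j + 1)
        for i, sent in enumerate(sentences)
        for j in range(len(sent))
    ]
    return make_corpus(language, [make_document(doc_id, sentences, spans)])


@pytest.fixture
def seed_lexicon_2():
    """Two seed pairs: (s1 -> S1) dim 0, (s2 -> S2) dim 1."""
    return SeedLexicon(
        pairs=[
            (TermType("zh", ("s1",)), TermType("en", ("e1",))),
            (TermType("zh", ("s2",)), TermType("en", ("e2",))),
        ]
    )


@pytest.fixture
def seed_lexicon_4():
    return SeedLexicon(
        pairs=[
            (TermType("zh", (f"s{i}",)), TermType("en", (f"e{i}",)))
            for i in range(4)
        ]
    )
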