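"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

import narraquery as nq
from narraquery.corpus_io import Corpus, Document, segment_sentences
from narraquery.frames import Binding, ConstituentKind


def make_document(doc_id: str, text: str) -> Document:
    return Document(id=doc_id, raw=text, sentences=tuple(segment_sentences(text)))


def make_corpus(texts: dict[str, str]) -> Corpus:
    return Corpus(
        documents=tuple(make_document(i, t) for i, t in sorted(texts.items()))
    )


def brute_force_matches(frame, sentence, lexicon):
    """Exhaustive reference matcher, independent of the engine.

    Enumerates every strictly increasing tuple of word-token positions and
    filters by constituent equality/membership and binding constraints.
    The token predicate is re-stated here rather than borrowed from the
    implementation.
    """
    words = sentence.word_tokens
    k = len(frame.constituents)
    hits = []
    for tup in itertools.combinations(range(len(words)), k):
        ok = True
        for cons, i in zip(frame.constituents, tup):
            form = words[i].surface.lower()
            if form == "xxx":
                ok = False
                break
            if cons.kind is ConstituentKind.LITERAL:
                if form != cons.value:
                    ok = False
                    break
            else:
                if form not in lexicon[cons.value].members:
                    ok = False
                    break
        if not ok:
            continue
        for b, i, j in zip(frame.bindings, tup, tup[1:]):
            if b is Binding.ADJACENT and j != i + 1:
                ok = False
                break
        if ok:
            hits.append(tup)
    return sorted(hits)


@pytest.fixture(scope="session")
def lexicon():
    return nq.default_lexicon()


@pytest.fixture(scope="session")
def queries():
    return nq.default_queries()
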