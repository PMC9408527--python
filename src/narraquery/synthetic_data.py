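"""Seeded synthetic patient-experience corpora with known ground truth.

Real narrative collections of this kind cannot be redistributed, so every
other module is exercised against generated stand-ins: short clinic-visit
stories built from a neutral filler-sentence pool, with sentences that
realize a query's frames planted into the texts that are meant to score
positive.  The generator controls

* the number of texts and the per-query prevalence of positives,
* the sentences-per-text range (default 3-23, the shape of a typical
  handwritten story collection),
* the probability that a simulated human reader flips a true label.

Label purity is guaranteed by construction *and* by screening: a planted
sentence must match its own query's frames and no other query's; filler
and distractor sentences must match no query at all.  With a fixed seed
the output is byte-identical.  The texts are deliberately plain — the
generator emulates corpus shape and planted content, not second-language
grammar or narrative style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Document, segment_sentences
from .frames import Binding, Constituent, ConstituentKind, Frame, match_frame
from .classifier import Query
from .evaluation import ReaderResponse
from .lexicon import Lexicon

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "simulate_readers",
]

#: Readers'-mean positive rates of the five default queries.
DEFAULT_PREVALENCE = {
    "Q1": 0.394,
    "Q2": 0.808,
    "Q3a": 0.769,
    "Q3b": 0.577,
    "Q4": 0.115,
}

# Neutral story sentences: clinic-visit flavor without any query vocabulary.
FILLER_SENTENCES = (
    "I remember that day very well.",
    "My friend came along with me.",
    "We waited for almost two hours.",
    "The waiting room was full of people.",
    "Everything happened very quickly.",
    "The building was big and clean.",
    "I had never been there before.",
    "We arrived early in the morning.",
    "Later we returned home by bus.",
    "My brother stayed with me the whole time.",
    "The weather outside was rainy.",
    "I filled some forms at the desk.",
    "People around us were quiet.",
    "After some time our number was called.",
    "It took a while to find the right room.",
    "The whole thing lasted one afternoon.",
    "I was quite nervous at first.",
    "In the end everything turned out fine.",
)

# Sentence pairs that split query vocabulary across a sentence boundary, to
# exercise the within-sentence constraint; each half matches nothing alone.
DISTRACTOR_PAIRS = (
    ("They used simple language with us.", "Problems never came up that day."),
    ("Everyone there understood us well.", "Not once did we have to wait."),
    ("The forms mentioned another date.", "Hospitals were not discussed at all."),
)

_OPENINGS = ("I remember", "My friend described", "The story involved", "That day brought")
_GAP_WORDS = ("of the", "with some", "at the", "in that", "from the")
_CLOSINGS = ("that day", "at the time", "during the stay", "")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    Defaults mirror a typical collection of 104 handwritten stories:
    3-23 sentences per text, and per-query positive rates equal to the
    mean rates two human readers reported for the five default questions.
    """

    n_texts: int = 104
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    sentences_range: tuple[int, int] = (3, 23)
    reader_flip_prob: float = 0.1
    distractor_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for qid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {qid} out of [0,1]: {p}")
        if not 0.0 <= self.reader_flip_prob < 0.5:
            raise ValueError("reader flip probability must be in [0, 0.5)")
        lo, hi = self.sentences_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad sentences range: {self.sentences_range}")


@dataclass(frozen=True)
class GroundTruth:
    """Intended document x query labels, 0/1."""

    labels: pd.DataFrame  # index doc_id, columns query ids

    def to_csv(self, path: str | Path) -> None:
        out = self.labels.copy()
        out.index.name = "doc_id"
        out.to_csv(path)


def _sentence_matches(sentence_text: str, frames, lexicon: Lexicon) -> bool:
    sents = segment_sentences(sentence_text)
    return any(
        match_frame(f, s, lexicon) for f in frames for s in sents
    )


def _matching_queries(sentence_text: str, queries, lexicon: Lexicon) -> set[str]:
    return {
        q.id for q in queries if _sentence_matches(sentence_text, q.frames, lexicon)
    }


def _realize_constituent(c: Constituent, lexicon: Lexicon, rng) -> str:
    if c.kind is ConstituentKind.LITERAL:
        return c.value
    members = sorted(lexicon[c.value].members)
    return members[rng.integers(len(members))]


def _realize_frame(frame: Frame, lexicon: Lexicon, rng) -> str:
    """Render one sentence that the frame matches, by construction."""
    parts = [_realize_constituent(frame.constituents[0], lexicon, rng)]
    for binding, cons in zip(frame.bindings, frame.constituents[1:]):
        if binding is Binding.WITHIN_SENTENCE:
            parts.append(_GAP_WORDS[rng.integers(len(_GAP_WORDS))])
        parts.append(_realize_constituent(cons, lexicon, rng))
    opening = _OPENINGS[rng.integers(len(_OPENINGS))]
    closing = _CLOSINGS[rng.integers(len(_CLOSINGS))]
    words = " ".join(p for p in (opening, *parts, closing) if p)
    return words[0].upper() + words[1:] + "."


def _plant_sentence(query: Query, queries, lexicon: Lexicon, rng) -> str:
    """A sentence matching exactly this query, screened against the others."""
    for _ in range(200):
        frame = query.frames[rng.integers(len(query.frames))]
        sent = _realize_frame(frame, lexicon, rng)
        if _matching_queries(sent, queries, lexicon) == {query.id}:
            return sent
    raise RuntimeError(
        f"could not realize a pure positive sentence for query {query.id}; "
        "the shipped frames of different queries may overlap too much"
    )


def generate_corpus(
    config: GeneratorConfig, lexicon: Lexicon, queries: list[Query]
) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus with planted positives and its ground truth.

    Each document draws its intended label per query from the configured
    prevalence; intended positives receive at least one planted sentence
    realized from that query's frames, and every other sentence is
    screened so that it matches no unintended query.
    """
    by_id = {q.id: q for q in queries}
    for qid in config.prevalence:
        if qid not in by_id:
            raise ValueError(f"prevalence given for unknown query {qid!r}")
    rng = np.random.default_rng(config.seed)
    qids = [q.id for q in queries]
    filler_pool = [
        s for s in FILLER_SENTENCES
        if not _matching_queries(s, queries, lexicon)
    ]
    distractor_pool = [
        pair for pair in DISTRACTOR_PAIRS
        if not _matching_queries(" ".join(pair), queries, lexicon)
    ]
    documents: list[Document] = []
    labels: dict[str, dict[str, int]] = {}
    width = len(str(config.n_texts))
    lo, hi = config.sentences_range
    for i in range(config.n_texts):
        doc_id = f"story_{i + 1:0{width}d}"
        intended = {
            qid: int(rng.random() < config.prevalence.get(qid, 0.0))
            for qid in qids
        }
        n_sent = int(rng.integers(lo, hi + 1))
        positives = [qid for qid in qids if intended[qid]]
        sentences: list[str] = []
        for qid in positives:
            sentences.append(_plant_sentence(by_id[qid], queries, lexicon, rng))
        while len(sentences) < n_sent:
            if (
                distractor_pool
                and n_sent - len(sentences) >= 2
                and rng.random() < config.distractor_prob
            ):
                pair = distractor_pool[rng.integers(len(distractor_pool))]
                sentences.extend(pair)
            else:
                sentences.append(filler_pool[rng.integers(len(filler_pool))])
        order = rng.permutation(len(sentences))
        raw = " ".join(sentences[j] for j in order)
        doc = Document(id=doc_id, raw=raw, sentences=tuple(segment_sentences(raw)))
        documents.append(doc)
        labels[doc_id] = intended
    corpus = Corpus(documents=tuple(documents))
    truth = GroundTruth(
        labels=pd.DataFrame.from_dict(labels, orient="index", columns=qids).astype(int)
    )
    return corpus, truth


def simulate_readers(
    truth: GroundTruth, flip_prob: float, seed: int
) -> tuple[ReaderResponse, ReaderResponse]:
    """Two simulated readers: each flips every true label independently.

    With flip probability ``p`` the expected raw inter-rater agreement is
    ``100 * ((1-p)^2 + p^2)`` — both readers right or both wrong.
    """
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip probability must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    base = truth.labels.to_numpy(dtype=int)
    readers = []
    for rid in ("reader1", "reader2"):
        flips = rng.random(base.shape) < flip_prob
        answers = np.where(flips, 1 - base, base)
        readers.append(
            ReaderResponse(
                reader_id=rid,
                answers=pd.DataFrame(
                    answers,
                    index=truth.labels.index,
                    columns=truth.labels.columns,
                ),
            )
        )
    return readers[0], readers[1]
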