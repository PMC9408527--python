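"""Reading, segmenting, tokenizing and summarizing narrative text collections.

A corpus is a directory of plain-text UTF-8 files, one patient-experience
story per file.  The texts follow an editorial convention imposed upstream:
each sentence starts with a capital letter and ends with a period, and any
word that could not be deciphered in the handwritten original is replaced by
the placeholder string ``xxx``.

Conventions implemented here:

* Sentences split at a period followed by whitespace or end of text; a
  period between two digits (a decimal point) never splits.  A trailing
  fragment without a period becomes a final sentence.
* Word tokens are maximal alphabetic runs; an apostrophe flanked by letters
  stays inside its token (``didn't`` is one token).  Digit runs and
  punctuation are emitted as non-word tokens so that character offsets stay
  recoverable, but every count and every matching rule considers word
  tokens only.
* All matching and type counting is done on the lowercased form, so
  sentence-initial capitals never defeat a lexicon lookup.
* The ``xxx`` placeholder counts as a word token (it stands for a real,
  unreadable word) but is flagged so that it can never satisfy a frame
  constituent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Token",
    "Sentence",
    "Document",
    "Corpus",
    "CorpusStats",
    "ILLEGIBLE",
    "load_corpus",
    "segment_sentences",
    "tokenize",
    "corpus_statistics",
]

#: Placeholder substituted upstream for illegible handwritten words.
ILLEGIBLE = "xxx"

# A word token: alphabetic run, optionally continued through internal
# apostrophes ("didn't", "o'clock").  Digit runs and single other glyphs are
# captured as non-word tokens.
_TOKEN_RE = re.compile(
    r"(?P<word>[^\W\d_]+(?:'[^\W\d_]+)*)|(?P<num>\d+(?:\.\d+)?)|(?P<punct>\S)"
)

# A period splits a sentence when followed by whitespace or end of text;
# "3.5" survives because its period is followed by a digit.
_SENT_SPLIT_RE = re.compile(r"\.(?=\s|$)")


@dataclass(frozen=True)
class Token:
    """One token of a sentence, with offsets into the sentence text."""

    surface: str
    start: int
    end: int
    is_word: bool

    @property
    def form(self) -> str:
        """Lowercased surface; the unit of all matching and type counting."""
        return self.surface.lower()

    @property
    def is_illegible(self) -> bool:
        """True when the token is the ``xxx`` illegible-word placeholder."""
        return self.is_word and self.form == ILLEGIBLE


@dataclass(frozen=True)
class Sentence:
    """A segmented sentence: its ordinal, text span and tokens."""

    index: int
    text: str
    tokens: tuple[Token, ...]

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.is_word)


@dataclass(frozen=True)
class Document:
    """One narrative text: identifier, raw text and segmented sentences."""

    id: str
    raw: str
    sentences: tuple[Sentence, ...]

    def word_tokens(self) -> Iterator[Token]:
        for sent in self.sentences:
            yield from sent.word_tokens


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of documents with unique ids."""

    documents: tuple[Document, ...]

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate document ids: {dupes}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)


@dataclass(frozen=True)
class CorpusStats:
    """Descriptive statistics for a text collection.

    ``types_mean`` is the corpus-wide distinct-type total divided by the
    number of texts (the convention of the summary table this mirrors),
    not the average of per-text type counts; the per-text extremes are
    still reported as ``types_min``/``types_max``.
    """

    n_texts: int
    sentences_total: int
    sentences_mean: float
    sentences_min: int
    sentences_max: int
    tokens_total: int
    tokens_mean: float
    tokens_min: int
    tokens_max: int
    types_total: int
    types_mean: float
    types_min: int
    types_max: int

    def to_rows(self) -> list[tuple[str, object, object, object, object]]:
        """Rows shaped like the standard text-collection summary table."""
        return [
            ("Texts", self.n_texts, "", "", ""),
            ("Sentences", self.sentences_total, self.sentences_mean,
             self.sentences_min, self.sentences_max),
            ("Wordform tokens", self.tokens_total, self.tokens_mean,
             self.tokens_min, self.tokens_max),
            ("Wordform types", self.types_total, self.types_mean,
             self.types_min, self.types_max),
        ]


def tokenize(sentence_text: str) -> list[Token]:
    """Tokenize one sentence into word and non-word tokens with offsets."""
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(sentence_text):
        tokens.append(
            Token(
                surface=m.group(0),
                start=m.start(),
                end=m.end(),
                is_word=m.lastgroup == "word",
            )
        )
    return tokens


def segment_sentences(text: str) -> list[Sentence]:
    """Split text into sentences at sentence-terminal periods.

    The terminal period itself is not part of the sentence text.  Empty
    candidates (e.g. produced by "..") are dropped; a trailing fragment
    with no period becomes the final sentence.
    """
    sentences: list[Sentence] = []
    pos = 0
    spans: list[str] = []
    for m in _SENT_SPLIT_RE.finditer(text):
        spans.append(text[pos:m.start()])
        pos = m.end()
    spans.append(text[pos:])
    for span in spans:
        stripped = span.strip()
        if not stripped:
            continue
        toks = tokenize(stripped)
        if not any(t.is_word for t in toks):
            continue
        sentences.append(
            Sentence(index=len(sentences), text=stripped, tokens=tuple(toks))
        )
    return sentences


def load_corpus(path: str | Path) -> Corpus:
    """Read every text file under ``path`` into a segmented corpus.

    Files are ordered by filename so corpora load deterministically.  The
    document id is the filename without its extension.

    Raises
    ------
    FileNotFoundError
        If the directory does not exist.
    ValueError
        If the directory holds no readable text file, or a file is not
        valid UTF-8 (the error names the file).
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no text files in corpus directory: {directory}")
    documents: list[Document] = []
    for p in files:
        try:
            raw = p.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise ValueError(f"file is not valid UTF-8: {p}") from exc
        documents.append(
            Document(id=p.stem, raw=raw, sentences=tuple(segment_sentences(raw)))
        )
    return Corpus(documents=tuple(documents))


def _round2(x: float) -> float:
    return round(x, 2)


def corpus_statistics(corpus: Corpus) -> CorpusStats:
    """Compute the text-collection summary (word tokens only).

    Types are distinct lowercased forms.  Means are reported to two
    decimals, each computed as total divided by the number of texts.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    n = len(corpus)
    sent_counts = [len(d.sentences) for d in corpus]
    tok_counts: list[int] = []
    type_counts: list[int] = []
    all_types: set[str] = set()
    for d in corpus:
        forms = [t.form for t in d.word_tokens()]
        tok_counts.append(len(forms))
        type_counts.append(len(set(forms)))
        all_types.update(forms)
    return CorpusStats(
        n_texts=n,
        sentences_total=sum(sent_counts),
        sentences_mean=_round2(sum(sent_counts) / n),
        sentences_min=min(sent_counts),
        sentences_max=max(sent_counts),
        tokens_total=sum(tok_counts),
        tokens_mean=_round2(sum(tok_counts) / n),
        tokens_min=min(tok_counts),
        tokens_max=max(tok_counts),
        types_total=len(all_types),
        types_mean=_round2(len(all_types) / n),
        types_min=min(type_counts),
        types_max=max(type_counts),
    )
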