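"""Lexical-syntactic frames: parsing and sentence-level matching.

A frame is an ordered sequence of constituents — literal wordforms or
references to lexicon word groups — joined by one of two binding operators:

``++`` (adjacent)
    the two constituents must match immediately successive word tokens;

``+`` (within-sentence)
    the two constituents must match word tokens in order somewhere inside
    the same sentence, adjacent or not.

The frame expression DSL::

    "not" ++ G:communication_verb
    G:illness_noun + "hospital" ++ G:facility_noun

Quoted strings are literals, ``G:<name>`` references a word group, and
whitespace is insignificant.  Frame files hold one expression per line,
with ``#`` starting a comment.

Matching semantics:

* A pattern never crosses a sentence boundary: the sentence is the search
  window, full stop.
* Matching sees word tokens only.  Punctuation is transparent — a comma
  between two words does not break their adjacency.
* Comparison is on lowercased forms; a group reference matches any token
  whose form is a member of the group.
* The illegible-word placeholder ``xxx`` never matches anything.
* All matches are returned, not just the first, so a classification can
  always be audited back to the exact tokens that produced it.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .corpus_io import Document, Sentence, Token
from .lexicon import Lexicon

__all__ = [
    "ConstituentKind",
    "Constituent",
    "Binding",
    "Frame",
    "FrameMatch",
    "FrameParseError",
    "parse_frame",
    "parse_frame_file",
    "match_frame",
    "match_document",
]


class ConstituentKind(enum.Enum):
    LITERAL = "literal"
    GROUP_REF = "group_ref"


class Binding(enum.Enum):
    ADJACENT = "++"
    WITHIN_SENTENCE = "+"


@dataclass(frozen=True)
class Constituent:
    """One slot of a frame: a literal wordform or a word-group reference."""

    kind: ConstituentKind
    value: str

    def matches(self, token: Token, lexicon: Lexicon) -> bool:
        if token.is_illegible or not token.is_word:
            return False
        if self.kind is ConstituentKind.LITERAL:
            return token.form == self.value
        return token.form in lexicon[self.value].members


@dataclass(frozen=True)
class Frame:
    """An ordered constituent sequence with a binding between each pair."""

    constituents: tuple[Constituent, ...]
    bindings: tuple[Binding, ...]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("frame needs at least one constituent")
        if len(self.bindings) != len(self.constituents) - 1:
            raise ValueError(
                "frame needs exactly one binding between consecutive constituents"
            )

    def group_refs(self) -> set[str]:
        return {
            c.value for c in self.constituents if c.kind is ConstituentKind.GROUP_REF
        }

    def relaxed(self) -> "Frame":
        """The same frame with every binding loosened to within-sentence."""
        return Frame(
            constituents=self.constituents,
            bindings=tuple(Binding.WITHIN_SENTENCE for _ in self.bindings),
            id=self.id,
        )


@dataclass(frozen=True)
class FrameMatch:
    """Where a frame matched: one word-token position per constituent.

    ``positions`` index into the sentence's word-token sequence (not the
    full token list), strictly increasing; for an adjacent binding the two
    positions are consecutive.
    """

    doc_id: str
    sentence_index: int
    positions: tuple[int, ...]


class FrameParseError(ValueError):
    """Raised on a malformed frame expression; carries the position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


_FRAME_TOKEN_RE = re.compile(
    r'\s*(?:(?P<adj>\+\+)|(?P<within>\+)|"(?P<lit>[^"]+)"'
    r"|G:(?P<group>[A-Za-z_][\w\-]*)|(?P<bad>\S))"
)


def parse_frame(expr: str, frame_id: str = "") -> Frame:
    """Parse one frame expression into a :class:`Frame`.

    The expression must alternate constituents and operators; a dangling
    operator, empty constituent or unknown token raises
    :class:`FrameParseError` with the character position.
    """
    constituents: list[Constituent] = []
    bindings: list[Binding] = []
    expect_constituent = True
    pos = 0
    for m in _FRAME_TOKEN_RE.finditer(expr):
        pos = m.start(m.lastgroup)
        if m.lastgroup == "bad":
            raise FrameParseError(f"unexpected token {m.group('bad')!r}", pos)
        if m.lastgroup in ("adj", "within"):
            if expect_constituent:
                raise FrameParseError("operator where a constituent was expected", pos)
            bindings.append(
                Binding.ADJACENT if m.lastgroup == "adj" else Binding.WITHIN_SENTENCE
            )
            expect_constituent = True
        else:
            if not expect_constituent:
                raise FrameParseError(
                    "constituent where an operator was expected", pos
                )
            if m.lastgroup == "lit":
                value = m.group("lit").strip().lower()
                if not value:
                    raise FrameParseError("empty literal constituent", pos)
                constituents.append(Constituent(ConstituentKind.LITERAL, value))
            else:
                constituents.append(
                    Constituent(ConstituentKind.GROUP_REF, m.group("group"))
                )
            expect_constituent = False
    if not constituents:
        raise FrameParseError("empty frame expression", 0)
    if expect_constituent:
        raise FrameParseError("dangling operator at end of expression", pos)
    return Frame(
        constituents=tuple(constituents), bindings=tuple(bindings), id=frame_id
    )


def parse_frame_file(path: str | Path) -> list[Frame]:
    """Parse a frame file: one expression per line, ``#`` comments allowed.

    Frame ids are ``<stem>:<lineno>``.
    """
    p = Path(path)
    frames: list[Frame] = []
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        frames.append(parse_frame(stripped, frame_id=f"{p.stem}:{lineno}"))
    return frames


def _check_refs(frame: Frame, lexicon: Lexicon) -> None:
    missing = sorted(g for g in frame.group_refs() if g not in lexicon)
    if missing:
        raise KeyError(
            f"frame {frame.id or '<anonymous>'} references unknown groups: {missing}"
        )


def match_frame(
    frame: Frame, sentence: Sentence, lexicon: Lexicon, doc_id: str = ""
) -> list[FrameMatch]:
    """Find every match of ``frame`` inside one sentence.

    Returns all matches, ordered by position tuple, each giving the
    word-token index matched by each constituent.  Word tokens are the
    search space: the adjacency operator requires consecutive *word*
    tokens, so intervening punctuation is ignored.
    """
    _check_refs(frame, lexicon)
    words = sentence.word_tokens
    n = len(words)
    k = len(frame.constituents)
    if n < k:
        return []
    # Positions each constituent can occupy, computed once.
    candidates = [
        [i for i in range(n) if c.matches(words[i], lexicon)]
        for c in frame.constituents
    ]
    matches: list[FrameMatch] = []

    def extend(ci: int, prefix: tuple[int, ...]) -> None:
        if ci == k:
            matches.append(
                FrameMatch(
                    doc_id=doc_id,
                    sentence_index=sentence.index,
                    positions=prefix,
                )
            )
            return
        for i in candidates[ci]:
            if ci > 0:
                prev = prefix[-1]
                if frame.bindings[ci - 1] is Binding.ADJACENT:
                    if i != prev + 1:
                        continue
                elif i <= prev:
                    continue
            extend(ci + 1, prefix + (i,))

    extend(0, ())
    matches.sort(key=lambda m: m.positions)
    return matches


def match_document(
    frame: Frame, doc: Document, lexicon: Lexicon
) -> list[FrameMatch]:
    """Concatenate per-sentence matches across a document, in order."""
    out: list[FrameMatch] = []
    for sent in doc.sentences:
        out.extend(match_frame(frame, sent, lexicon, doc_id=doc.id))
    return out
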