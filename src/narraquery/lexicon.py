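"""The semantic-syntactic word-group lexicon and corpus frequency lists.

The lexicon is a set of named word groups.  Each group collects the
inflected wordforms (no lemmatization — every inflection is listed
explicitly) of one semantic category, usually of one syntactic class, e.g.
a group of physician nouns or of communication verbs.  Membership is
deliberately non-exclusive: a form such as "medical" may sit in an
adjective group and in a noun group at once.

Groups are stored on disk as comma-separated text files, one file per
group, the filename (minus extension) being the group name.  An optional
first line of the form ``#semantic=<label>,syntactic=<label>`` carries the
group's labels.

Lexicon construction starts from a corpus frequency list; filtering that
list to forms of at least four letters removes most high-frequency
closed-class function words, leaving the content words from which groups
are curated by hand.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import Corpus

__all__ = [
    "FrequencyList",
    "WordGroup",
    "Lexicon",
    "GroupRelation",
    "frequency_list",
    "filter_short_words",
    "load_lexicon",
    "groups_of",
    "group_relation",
]


@dataclass(frozen=True)
class FrequencyList:
    """Wordform type/token tallies, descending by count then alphabetical."""

    entries: tuple[tuple[str, int], ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def forms(self) -> list[str]:
        return [form for form, _ in self.entries]


@dataclass(frozen=True)
class WordGroup:
    """A named, labelled set of lowercased wordforms."""

    name: str
    members: frozenset[str]
    semantic_label: str = ""
    syntactic_label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"word group {self.name!r} has no members")
        bad = [m for m in self.members if m != m.lower()]
        if bad:
            raise ValueError(f"group {self.name!r} has non-lowercase members: {bad}")

    def __contains__(self, form: str) -> bool:
        return form.lower() in self.members


class GroupRelation(enum.Enum):
    """Set relation between two word groups."""

    INDEPENDENT = "independent"
    OVERLAPPING = "overlapping"
    SUBORDINATE = "subordinate"
    SUPERORDINATE = "superordinate"
    EQUAL = "equal"


@dataclass(frozen=True)
class Lexicon:
    """Word groups keyed by unique name; membership may overlap."""

    groups: dict[str, WordGroup]

    def __post_init__(self) -> None:
        for name, grp in self.groups.items():
            if name != grp.name:
                raise ValueError(f"group keyed {name!r} is named {grp.name!r}")

    def __getitem__(self, name: str) -> WordGroup:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def __len__(self) -> int:
        return len(self.groups)

    def groups_of(self, form: str) -> set[str]:
        """Names of every group containing ``form`` (case-insensitive)."""
        f = form.lower()
        return {name for name, grp in self.groups.items() if f in grp.members}


def frequency_list(corpus: Corpus) -> FrequencyList:
    """Tally every distinct lowercased wordform across the corpus."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(t.form for t in doc.word_tokens())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return FrequencyList(entries=tuple(ordered))


def filter_short_words(freq: FrequencyList, min_len: int = 4) -> FrequencyList:
    """Drop forms shorter than ``min_len`` characters (order preserved).

    With the default of four letters this removes most high-frequency
    function words (articles, prepositions, auxiliaries), which in English
    are predominantly one to three letters long.  Apostrophes count toward
    the length.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = tuple((f, c) for f, c in freq.entries if len(f) >= min_len)
    return FrequencyList(entries=kept)


def _parse_group_file(path: Path) -> WordGroup:
    text = path.read_text(encoding="utf-8")
    semantic = syntactic = ""
    lines = text.splitlines()
    body_lines = []
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("#"):
            header = stripped.lstrip("#").strip()
            for part in header.split(","):
                key, _, value = part.partition("=")
                key = key.strip().lower()
                if key == "semantic":
                    semantic = value.strip()
                elif key == "syntactic":
                    syntactic = value.strip()
            continue
        body_lines.append(line)
    members = frozenset(
        w.strip().lower()
        for line in body_lines
        for w in line.split(",")
        if w.strip()
    )
    if not members:
        raise ValueError(f"empty word-group file for group {path.stem!r}: {path}")
    return WordGroup(
        name=path.stem,
        members=members,
        semantic_label=semantic,
        syntactic_label=syntactic,
    )


def load_lexicon(path: str | Path) -> Lexicon:
    """Load every ``.csv``/``.txt`` group file in a directory into a Lexicon.

    Raises
    ------
    FileNotFoundError
        If the directory does not exist.
    ValueError
        On an empty group file (naming the group) or duplicate group names.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"lexicon directory not found: {directory}")
    groups: dict[str, WordGroup] = {}
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in {".csv", ".txt"}
    )
    if not files:
        raise ValueError(f"no group files in lexicon directory: {directory}")
    for p in files:
        grp = _parse_group_file(p)
        if grp.name in groups:
            raise ValueError(f"duplicate group name: {grp.name!r}")
        groups[grp.name] = grp
    return Lexicon(groups=groups)


def groups_of(lexicon: Lexicon, form: str) -> set[str]:
    """Names of every lexicon group containing ``form`` (case-insensitive)."""
    return lexicon.groups_of(form)


def group_relation(g1: WordGroup, g2: WordGroup) -> GroupRelation:
    """Classify the set relation between two groups.

    ``subordinate`` means g1 is a proper subset of g2 (e.g. a group of
    negative event nouns inside the group of all event nouns);
    ``superordinate`` is the converse; ``independent`` means the member
    sets are disjoint; any partial intersection is ``overlapping``.
    """
    a, b = g1.members, g2.members
    if a == b:
        return GroupRelation.EQUAL
    if a < b:
        return GroupRelation.SUBORDINATE
    if a > b:
        return GroupRelation.SUPERORDINATE
    if a & b:
        return GroupRelation.OVERLAPPING
    return GroupRelation.INDEPENDENT
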