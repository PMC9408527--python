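"""Binary query classification of narrative texts.

Each research question is operationalized as a *query*: the question text
plus a set of lexical-syntactic frames that encode the statements counted
as a "yes".  A text scores 1 for a query when at least one of the query's
frames matches anywhere in the text, and 0 otherwise.  Every positive cell
keeps the supporting matches as an audit trail, because the point of
benchmarking against human readers is being able to see *why* a text was
classified positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from .corpus_io import Corpus, Document
from .frames import Frame, FrameMatch, match_document, parse_frame_file
from .lexicon import Lexicon

__all__ = [
    "Query",
    "ClassificationResult",
    "QuerySummary",
    "load_queries",
    "classify_document",
    "classify_corpus",
    "summarize",
    "percent",
]


@dataclass(frozen=True)
class Query:
    """A dichotomous question backed by a non-empty frame set."""

    id: str
    question_text: str
    frames: tuple[Frame, ...]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError(f"query {self.id} has no frames")


@dataclass(frozen=True)
class ClassificationResult:
    """Document x query 0/1 score matrix plus the per-cell match audit."""

    scores: pd.DataFrame  # index: doc_id, columns: query ids, values 0/1
    audit: dict[tuple[str, str], tuple[FrameMatch, ...]]

    def score(self, doc_id: str, query_id: str) -> int:
        return int(self.scores.at[doc_id, query_id])

    def to_csv(self, path: str | Path) -> None:
        """Write the classic one-row-per-document results file."""
        out = self.scores.copy()
        out.index.name = "doc_id"
        out.to_csv(path)


@dataclass(frozen=True)
class QuerySummary:
    """Positive counts and one-decimal percentages per query."""

    counts: dict[str, int]
    percents: dict[str, float]
    n_texts: int


def percent(count: float, n: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding, as printed in summary tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(str(count)) / Decimal(n)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def load_queries(config_path: str | Path) -> list[Query]:
    """Load a query configuration (YAML) mapping ids to frame files.

    Shape::

        queries:
          - id: Q1
            question: Does the text mention any difficulties ... ?
            frames: [frames/q1.txt]

    Frame paths are resolved relative to the config file.
    """
    cfg_path = Path(config_path)
    cfg = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))
    queries: list[Query] = []
    seen: set[str] = set()
    for entry in cfg["queries"]:
        qid = str(entry["id"])
        if qid in seen:
            raise ValueError(f"duplicate query id: {qid}")
        seen.add(qid)
        frames: list[Frame] = []
        for rel in entry["frames"]:
            frames.extend(parse_frame_file(cfg_path.parent / rel))
        queries.append(
            Query(id=qid, question_text=str(entry.get("question", "")),
                  frames=tuple(frames))
        )
    return queries


def classify_document(doc: Document, query: Query, lexicon: Lexicon) -> int:
    """1 iff any frame of the query matches anywhere in the document."""
    for frame in query.frames:
        if match_document(frame, doc, lexicon):
            return 1
    return 0


def classify_corpus(
    corpus: Corpus, queries: list[Query], lexicon: Lexicon
) -> ClassificationResult:
    """Score every document against every query, keeping the match audit."""
    if not queries:
        raise ValueError("no queries given")
    ids = [q.id for q in queries]
    if len(ids) != len(set(ids)):
        raise ValueError("query ids must be unique within a run")
    audit: dict[tuple[str, str], tuple[FrameMatch, ...]] = {}
    rows: dict[str, dict[str, int]] = {}
    for doc in corpus:
        row: dict[str, int] = {}
        for query in queries:
            cell_matches: list[FrameMatch] = []
            for frame in query.frames:
                cell_matches.extend(match_document(frame, doc, lexicon))
            row[query.id] = 1 if cell_matches else 0
            if cell_matches:
                audit[(doc.id, query.id)] = tuple(cell_matches)
        rows[doc.id] = row
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=ids).astype(int)
    scores = scores.loc[[d.id for d in corpus]]
    return ClassificationResult(scores=scores, audit=audit)


def summarize(result: ClassificationResult, n_texts: int) -> QuerySummary:
    """Per-query positive counts and percentages of the text collection."""
    if n_texts < 1:
        raise ValueError("n_texts must be >= 1")
    counts = {q: int(result.scores[q].sum()) for q in result.scores.columns}
    percents = {q: percent(c, n_texts) for q, c in counts.items()}
    return QuerySummary(counts=counts, percents=percents, n_texts=n_texts)
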