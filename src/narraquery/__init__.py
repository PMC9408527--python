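"""narraquery: rule-based information extraction from patient-experience narratives.

The package answers closed-ended dichotomous questions about free-text
clinic-visit stories by matching lexical-syntactic frames — ordered
sequences of wordforms and word-group references bound adjacently (``++``)
or within one sentence (``+``) — and benchmarks the automatic answers
against human readers via consensus ranks and Spearman rank correlation.
"""

from importlib import resources as _resources
from pathlib import Path as _Path

from .corpus_io import (
    Corpus,
    CorpusStats,
    Document,
    Sentence,
    Token,
    corpus_statistics,
    load_corpus,
    segment_sentences,
    tokenize,
)
from .lexicon import (
    FrequencyList,
    GroupRelation,
    Lexicon,
    WordGroup,
    filter_short_words,
    frequency_list,
    group_relation,
    groups_of,
    load_lexicon,
)
from .frames import (
    Binding,
    Constituent,
    Frame,
    FrameMatch,
    FrameParseError,
    match_document,
    match_frame,
    parse_frame,
    parse_frame_file,
)
from .classifier import (
    ClassificationResult,
    Query,
    QuerySummary,
    classify_corpus,
    classify_document,
    load_queries,
    summarize,
)
from .evaluation import (
    EvalReport,
    ReaderResponse,
    SpearmanResult,
    build_report,
    consensus_rank,
    interrater_agreement,
    read_reader_responses,
    spearman,
)
from .synthetic_data import (
    GeneratorConfig,
    GroundTruth,
    generate_corpus,
    simulate_readers,
)

__version__ = "0.1.0"

_DATA_DIR = _Path(__file__).parent / "data"


def default_lexicon() -> Lexicon:
    """The shipped illustrative word-group lexicon."""
    return load_lexicon(_DATA_DIR / "lexicon")


def default_queries() -> list[Query]:
    """The five shipped queries with their illustrative frame sets."""
    return load_queries(_DATA_DIR / "queries.yaml")
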