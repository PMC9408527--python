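"""Benchmarking automatic classifications against two human readers.

Two readers independently answer each dichotomous question for every text.
Their slight disagreements are absorbed by converting the pair of yes/no
answers into a three-level consensus rank per text: 1 when both said yes,
0.5 when they split, 0 when both said no.  The automatic 0/1 scores are
then compared with the consensus vector per question using the Spearman
rank correlation (midranks for the massive ties such data produce), and
raw inter-rater agreement is reported alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassificationResult, percent

__all__ = [
    "ReaderResponse",
    "SpearmanResult",
    "EvalReport",
    "read_reader_responses",
    "interrater_agreement",
    "consensus_rank",
    "spearman",
    "build_report",
]

_PERMUTATION_N = 10  # below this, the p-value is exact by enumeration


@dataclass(frozen=True)
class ReaderResponse:
    """One reader's yes/no answers: document x query, values in {0, 1}."""

    reader_id: str
    answers: pd.DataFrame  # index doc_id, columns query ids, values 0/1

    def vector(self, query_id: str) -> np.ndarray:
        return self.answers[query_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman rho with its p-value; degenerate inputs are flagged."""

    rho: float
    p_value: float
    undefined: bool = False

    def __iter__(self):
        return iter((self.rho, self.p_value))


@dataclass(frozen=True)
class EvalReport:
    """Per-query benchmark of the automatic scores against two readers."""

    table: pd.DataFrame  # one row per query
    n_texts: int

    def table2(self) -> pd.DataFrame:
        """Count/percent columns for readers, their mean, and the script."""
        cols = [
            "reader1_count", "reader1_pct", "reader2_count", "reader2_pct",
            "readers_mean_count", "readers_mean_pct",
            "script_count", "script_pct",
        ]
        return self.table[cols]

    def table3(self) -> pd.DataFrame:
        """Spearman correlation of script vs consensus ranks, per query."""
        return self.table[["question", "rho", "p_value", "agreement_pct"]]


def read_reader_responses(path) -> list[ReaderResponse]:
    """Read a ``doc_id,reader_id,Q1,...`` CSV with yes/no cells."""
    df = pd.read_csv(path, dtype=str)
    required = {"doc_id", "reader_id"}
    if not required <= set(df.columns):
        raise ValueError(f"reader file must have columns {sorted(required)}")
    query_cols = [c for c in df.columns if c not in required]
    out: list[ReaderResponse] = []
    for reader_id, grp in df.groupby("reader_id", sort=True):
        answers = grp.set_index("doc_id")[query_cols].map(
            lambda v: 1 if str(v).strip().lower() in {"yes", "y", "1"} else 0
        )
        out.append(ReaderResponse(reader_id=str(reader_id), answers=answers))
    return out


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def interrater_agreement(r1, r2) -> float:
    """Percent of positions where two answer vectors agree, to 1 decimal."""
    a, b = _as_array(r1), _as_array(r2)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty answer vectors")
    return percent(int(np.sum(a == b)), a.size)


def consensus_rank(r1, r2) -> np.ndarray:
    """Elementwise consensus of two yes/no vectors: 1, 0.5 or 0."""
    a, b = _as_array(r1), _as_array(r2)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def _rho_midrank(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(auto, consensus) -> SpearmanResult:
    """Spearman rank correlation of automatic scores vs consensus ranks.

    Ranks use the midrank (average) convention, mandatory for vectors this
    heavily tied; rho is the product-moment correlation of the ranks.  The
    two-sided p-value uses the t approximation for n >= 10 and exhaustive
    permutation of one vector below that.  A constant vector leaves the
    correlation undefined, which is flagged rather than returned as a
    silent NaN.
    """
    x, y = _as_array(auto), _as_array(consensus)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=math.nan, p_value=math.nan, undefined=True)
    rho = _rho_midrank(x, y)
    if n >= _PERMUTATION_N:
        # t = rho * sqrt((n-2)/(1-rho^2)), two-sided
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        # Exact two-sided p: enumerate all n! orderings of one rank vector.
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(rx)), dtype=float)
        pc = perms - perms.mean(axis=1, keepdims=True)
        yc = ry - ry.mean()
        denom = np.sqrt((pc * pc).sum(axis=1) * (yc * yc).sum())
        rhos = (pc @ yc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return SpearmanResult(rho=rho, p_value=float(p))


def build_report(
    results: ClassificationResult,
    r1: ReaderResponse,
    r2: ReaderResponse,
    n_texts: int | None = None,
) -> EvalReport:
    """Assemble the full per-query benchmark report.

    For each query: both readers' positive counts and percentages, their
    mean, the script's count and percentage, raw inter-rater agreement,
    and the Spearman correlation of script scores against the 0/0.5/1
    consensus ranks.  Readers and script must cover exactly the same
    documents and queries.
    """
    doc_ids = list(results.scores.index)
    query_ids = list(results.scores.columns)
    if n_texts is None:
        n_texts = len(doc_ids)
    for resp in (r1, r2):
        missing_docs = set(doc_ids) - set(resp.answers.index)
        missing_queries = set(query_ids) - set(resp.answers.columns)
        if missing_docs or missing_queries:
            raise ValueError(
                f"reader {resp.reader_id} is missing documents "
                f"{sorted(missing_docs)} / queries {sorted(missing_queries)}"
            )
    rows = []
    for qid in query_ids:
        a1 = r1.answers.loc[doc_ids, qid].to_numpy(dtype=float)
        a2 = r2.answers.loc[doc_ids, qid].to_numpy(dtype=float)
        auto = results.scores[qid].to_numpy(dtype=float)
        c1, c2 = int(a1.sum()), int(a2.sum())
        mean_count = (c1 + c2) / 2.0
        consensus = consensus_rank(a1, a2)
        sp = spearman(auto, consensus)
        rows.append(
            {
                "query": qid,
                "question": "",
                "reader1_count": c1,
                "reader1_pct": percent(c1, n_texts),
                "reader2_count": c2,
                "reader2_pct": percent(c2, n_texts),
                "readers_mean_count": mean_count,
                "readers_mean_pct": percent(mean_count, n_texts),
                "script_count": int(auto.sum()),
                "script_pct": percent(int(auto.sum()), n_texts),
                "agreement_pct": interrater_agreement(a1, a2),
                "rho": round(sp.rho, 3) if not sp.undefined else math.nan,
                "p_value": sp.p_value,
                "rho_undefined": sp.undefined,
            }
        )
    table = pd.DataFrame(rows).set_index("query")
    return EvalReport(table=table, n_texts=n_texts)
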