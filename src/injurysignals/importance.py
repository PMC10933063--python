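"""Term importance: per-year TF-IDF with the max-TF convention, and
selection of the top-K candidate injury keywords by average annual weight.

For a term t in year y the weight is ``tfidf(t, y) = tf_max(t, y) * idf(t, y)``
where ``tf(t, d) = count(t, d) / len(d)`` and
``idf(t, y) = ln(n_docs(y) / df(t, y))``; ``tf_max`` is the maximum tf over
the year's documents containing t.  Candidate keywords are the K terms
with the largest average annual TF-IDF.  A term absent from a year (DF
below the support threshold there) contributes, under the default
``zero`` policy, a zero to its average over all study years; the
alternative ``observed`` policy averages over the years the term was
retained.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .preprocess import ConfigurationError, YearlyTermMatrix

logger = logging.getLogger(__name__)

MissingYearPolicy = Literal["zero", "observed"]


@dataclass(frozen=True)
class TermYearWeight:
    term: str
    year: int
    tf_max: float
    idf: float
    tfidf: float


@dataclass(frozen=True)
class CandidateKeyword:
    term: str
    yearly_weights: dict[int, float]
    avg_tfidf: float
    rank: int


def tf(term_count_in_doc: int, doc_token_total: int) -> float:
    """Term frequency: occurrences of the term over total tokens in the doc."""
    if doc_token_total < 1:
        raise ValueError("zero-length document reached tf(); drop it upstream")
    if not 0 <= term_count_in_doc <= doc_token_total:
        raise ValueError(
            f"term count {term_count_in_doc} outside [0, {doc_token_total}]"
        )
    return term_count_in_doc / doc_token_total


def idf(n_docs: int, n_docs_with_term: int) -> float:
    """Inverse document frequency: natural log of total docs over docs with term."""
    if n_docs_with_term < 1:
        raise ValueError("idf undefined for a term absent from the corpus")
    if n_docs_with_term > n_docs:
        raise ValueError(f"df {n_docs_with_term} exceeds corpus size {n_docs}")
    return math.log(n_docs / n_docs_with_term)


def yearly_tfidf(matrix: YearlyTermMatrix) -> list[TermYearWeight]:
    """TF-IDF per retained term for one year, using the max-TF convention:
    a term's tf is the maximum over that year's documents containing it."""
    out: list[TermYearWeight] = []
    for term in matrix.terms():
        docs = matrix.term_in_doc_count[term]
        tf_max = max(tf(c, matrix.doc_token_total[d]) for d, c in docs.items())
        w = idf(matrix.docs, len(docs))
        out.append(TermYearWeight(term, matrix.year, tf_max, w, tf_max * w))
    return out


def select_candidates(
    weights: Iterable[TermYearWeight],
    k: int = 300,
    missing_year_policy: MissingYearPolicy = "zero",
    study_years: Iterable[int] | None = None,
) -> list[CandidateKeyword]:
    """Top-k terms by average annual TF-IDF.

    ``study_years`` defaults to the distinct years present in ``weights``.
    Ties in the average (after rounding to 12 decimals) are broken by
    lexicographic term order for cross-platform determinism.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if missing_year_policy not in ("zero", "observed"):
        raise ConfigurationError(f"unknown missing_year_policy {missing_year_policy!r}")
    weights = list(weights)
    years = sorted(set(study_years)) if study_years is not None else sorted(
        {w.year for w in weights}
    )
    if not years:
        return []
    by_term: dict[str, dict[int, float]] = {}
    for w in weights:
        by_term.setdefault(w.term, {})[w.year] = w.tfidf
    rows: list[tuple[float, str, dict[int, float]]] = []
    for term, yearly in by_term.items():
        if missing_year_policy == "zero":
            avg = sum(yearly.get(y, 0.0) for y in years) / len(years)
        else:
            avg = sum(yearly.values()) / len(yearly)
        rows.append((round(avg, 12), term, yearly))
    rows.sort(key=lambda r: (-r[0], r[1]))
    if len(rows) < k:
        logger.warning("only %d terms available for top-%d selection", len(rows), k)
    return [
        CandidateKeyword(term=t, yearly_weights=dict(y), avg_tfidf=a, rank=i + 1)
        for i, (a, t, y) in enumerate(rows[:k])
    ]


def write_candidate_table(
    candidates: Iterable[CandidateKeyword],
    path: str | Path,
    study_years: Iterable[int] | None = None,
) -> None:
    """Write the candidate keyword table: one row per term, one column per
    year (blank where the term was absent), average and rank."""
    candidates = list(candidates)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if study_years is not None:
        years = sorted(set(study_years))
    else:
        years = sorted({y for c in candidates for y in c.yearly_weights})
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "term", *years, "avg_tfidf"])
        for c in candidates:
            row: list[str] = [str(c.rank), c.term]
            for y in years:
                w = c.yearly_weights.get(y)
                row.append("" if w is None else f"{w:.6f}")
            row.append(f"{c.avg_tfidf:.6f}")
            writer.writerow(row)
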