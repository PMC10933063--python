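"""Corpus preprocessing: tokenization and per-year term-document matrices.

Free-text incident narratives (one per casualty event) are tokenized,
aggregated into one term-document structure per calendar year, and downsized
to terms whose document frequency (DF) meets a minimum support threshold.
The DF threshold is applied within each year; the final vocabulary is the
union of the per-year retained term sets.

Tokenization is pluggable: morphological analyzers for agglutinative
languages (e.g. Korean noun extraction) can be registered under a name and
selected by configuration.  The default tokenizer is language-agnostic:
lowercase, split on non-word characters, drop tokens shorter than two
characters and tokens that are pure digits.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

logger = logging.getLogger(__name__)

Tokenizer = Callable[[str], list[str]]


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (empty corpus, missing egos, ...)."""


class ConfigurationError(ValueError):
    """Invalid configuration value (unknown tokenizer, bad threshold, ...)."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncidentRecord:
    """One casualty event: identifier, calendar year, free-text narrative."""

    id: str
    year: int
    text: str


def read_records(path: str | Path) -> list[IncidentRecord]:
    """Read incident records from a JSON-lines or CSV file.

    Both formats carry the columns/keys ``id``, ``year``, ``text``.  The
    format is chosen by file suffix (``.jsonl``/``.json`` vs ``.csv``).
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"input file not found: {path}")
    records: list[IncidentRecord] = []
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                records.append(
                    IncidentRecord(str(obj["id"]), int(obj["year"]), str(obj["text"]))
                )
    else:
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    IncidentRecord(str(row["id"]), int(row["year"]), str(row["text"]))
                )
    return records


def write_records(records: Iterable[IncidentRecord], path: str | Path) -> None:
    """Write records as JSON-lines or CSV depending on the file suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        with path.open("w") as fh:
            for r in records:
                fh.write(json.dumps({"id": r.id, "year": r.year, "text": r.text}) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "year", "text"])
            for r in records:
                writer.writerow([r.id, r.year, r.text])


# ---------------------------------------------------------------------------
# Tokenizers
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\w+", re.UNICODE)
_TOKENIZERS: dict[str, Tokenizer] = {}


def register_tokenizer(name: str) -> Callable[[Tokenizer], Tokenizer]:
    """Decorator registering a tokenizer under ``name``."""

    def deco(fn: Tokenizer) -> Tokenizer:
        _TOKENIZERS[name] = fn
        return fn

    return deco


def get_tokenizer(name: str) -> Tokenizer:
    try:
        return _TOKENIZERS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown tokenizer {name!r}; registered: {sorted(_TOKENIZERS)}"
        ) from None


@register_tokenizer("default")
def default_tokenizer(text: str) -> list[str]:
    """Lowercase word-split tokenizer.

    Splits on non-word characters, lowercases, and drops tokens of length
    < 2 as well as pure-digit tokens (both carry little injury-mechanism
    information and mostly reflect record formatting).
    """
    tokens = _WORD_RE.findall(text.lower())
    return [t for t in tokens if len(t) >= 2 and not t.isdigit()]


@register_tokenizer("whitespace")
def whitespace_tokenizer(text: str) -> list[str]:
    """Plain whitespace split, no folding — for pre-tokenized input."""
    return text.split()


def tokenize(text: str, tokenizer: Tokenizer | str = "default") -> list[str]:
    """Tokenize one narrative with the given (or named) tokenizer."""
    fn = get_tokenizer(tokenizer) if isinstance(tokenizer, str) else tokenizer
    return fn(text)


# ---------------------------------------------------------------------------
# Yearly term-document matrices
# ---------------------------------------------------------------------------


@dataclass
class YearlyTermMatrix:
    """Term-document counts for one calendar year.

    ``term_in_doc_count[t][d]`` is the number of occurrences of term ``t``
    in document ``d`` (present only when >= 1); ``doc_token_total[d]`` is
    the total token count of document ``d`` computed *before* any term
    filtering, so term-frequency denominators always refer to the full
    written narrative.
    """

    year: int
    docs: int
    term_in_doc_count: dict[str, dict[str, int]] = field(default_factory=dict)
    doc_token_total: dict[str, int] = field(default_factory=dict)

    @property
    def term_doc_count(self) -> dict[str, int]:
        """Document frequency: number of documents containing each term."""
        return {t: len(d) for t, d in self.term_in_doc_count.items()}

    def terms(self) -> list[str]:
        return sorted(self.term_in_doc_count)


def build_matrix(
    records: Iterable[IncidentRecord],
    tokenizer: Tokenizer | str = "default",
) -> list[YearlyTermMatrix]:
    """Build one :class:`YearlyTermMatrix` per distinct year.

    Records whose narrative is empty after tokenization are dropped (their
    count is logged).  Raises :class:`PipelineError` when nothing survives.
    """
    fn = get_tokenizer(tokenizer) if isinstance(tokenizer, str) else tokenizer
    by_year: dict[int, YearlyTermMatrix] = {}
    dropped = 0
    for rec in records:
        tokens = fn(rec.text)
        if not tokens:
            dropped += 1
            continue
        mat = by_year.get(rec.year)
        if mat is None:
            mat = by_year[rec.year] = YearlyTermMatrix(year=rec.year, docs=0)
        mat.docs += 1
        mat.doc_token_total[rec.id] = len(tokens)
        for tok in tokens:
            mat.term_in_doc_count.setdefault(tok, {})
            mat.term_in_doc_count[tok][rec.id] = (
                mat.term_in_doc_count[tok].get(rec.id, 0) + 1
            )
    if dropped:
        logger.info("dropped %d records empty after tokenization", dropped)
    if not by_year:
        raise PipelineError("all records empty after tokenization")
    return [by_year[y] for y in sorted(by_year)]


def downsize(matrix: YearlyTermMatrix, min_df: int = 10) -> YearlyTermMatrix:
    """Keep only terms appearing in at least ``min_df`` documents.

    The threshold is inclusive (DF >= min_df retains).  Document counts and
    token totals are untouched, so downsizing is idempotent and never
    changes term-frequency denominators.
    """
    if min_df < 1:
        raise ConfigurationError(f"min_df must be >= 1, got {min_df}")
    kept = {
        t: dict(docs)
        for t, docs in matrix.term_in_doc_count.items()
        if len(docs) >= min_df
    }
    removed = len(matrix.term_in_doc_count) - len(kept)
    if removed:
        logger.debug("year %d: DF<%d removed %d terms", matrix.year, min_df, removed)
    if not kept:
        logger.warning("year %d: no terms survive DF>=%d", matrix.year, min_df)
    return YearlyTermMatrix(
        year=matrix.year,
        docs=matrix.docs,
        term_in_doc_count=kept,
        doc_token_total=dict(matrix.doc_token_total),
    )


def union_terms(matrices: Iterable[YearlyTermMatrix]) -> list[str]:
    """Sorted de-duplicated union of retained terms across years."""
    matrices = list(matrices)
    if not matrices:
        raise PipelineError("union_terms requires at least one matrix")
    out: set[str] = set()
    for m in matrices:
        out.update(m.term_in_doc_count)
    return sorted(out)


def write_matrix_summary(matrices: Iterable[YearlyTermMatrix], path: str | Path) -> None:
    """Write a per-year term summary CSV: year, term, df, tf_max."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "term", "df", "tf_max"])
        for m in matrices:
            for term in m.terms():
                docs = m.term_in_doc_count[term]
                tf_max = max(c / m.doc_token_total[d] for d, c in docs.items())
                writer.writerow([m.year, term, len(docs), f"{tf_max:.6g}"])


def iter_doc_term_sets(matrix: YearlyTermMatrix) -> Iterator[tuple[str, set[str]]]:
    """Yield (doc_id, set of retained terms present) for each document."""
    per_doc: dict[str, set[str]] = {d: set() for d in matrix.doc_token_total}
    for term, docs in matrix.term_in_doc_count.items():
        for d in docs:
            per_doc[d].add(term)
    for d in sorted(per_doc):
        yield d, per_doc[d]
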