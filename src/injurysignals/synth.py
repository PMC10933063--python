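"""Synthetic EMS-narrative corpus generator with known ground truth.

Real incident narratives from national emergency-response logbooks are not
publicly deposited, so every downstream stage of the pipeline is validated
against corpora generated here.  The generator plants two kinds of signal
on top of a Zipf-distributed background vocabulary:

* **term trajectories** — per planted term, a yearly document-presence rate
  following one of four shapes (``hazardous``: frequent, rising, volatile;
  ``noteworthy``: rare, rising, volatile; ``diffusion``: frequent,
  declining; ``flat``: constant), so the categorization stage has a known
  answer key;
* **co-occurrence blocks** — groups of terms that appear together within
  documents far more often than across groups, so community detection on
  the phi network has a known partition to recover.

Documents are bags of tokens joined by single spaces, which the default
tokenizer inverts exactly; generation is fully deterministic given the
spec's integer seed (per-year substreams are derived from it).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .preprocess import IncidentRecord, write_records

TrajectoryKind = Literal["hazardous", "noteworthy", "diffusion", "flat"]

CATEGORIES = ("hazardous", "noteworthy", "diffusion", "unclassified")


class SpecValidationError(ValueError):
    """A synthetic-corpus spec violates one of its invariants."""


# Default trajectory shapes, as fractions of incidents_per_year.
# base: mean presence rate; slope: change per year; sigma: lognormal
# year-effect scale injecting volatility without changing the mean rate.
_KIND_DEFAULTS: dict[str, dict[str, float]] = {
    "hazardous": {"base_frac": 0.55, "slope_frac": 0.050, "sigma": 0.5},
    "noteworthy": {"base_frac": 0.05, "slope_frac": 0.012, "sigma": 0.6},
    "diffusion": {"base_frac": 0.55, "slope_frac": -0.050, "sigma": 0.1},
    "flat": {"base_frac": 0.10, "slope_frac": 0.0, "sigma": 0.15},
}


@dataclass(frozen=True)
class PlantedTerm:
    """A vocabulary item with a controlled yearly document-frequency path.

    ``base_rate`` is the expected number of documents per year containing
    the term at mid-study; ``slope`` the expected change in that number per
    year; ``sigma`` the scale of the multiplicative lognormal year effect
    (mean-one), which raises between-year volatility without moving the
    average rate.
    """

    term: str
    trajectory_kind: TrajectoryKind
    base_rate: float
    slope: float = 0.0
    sigma: float = 0.0

    @classmethod
    def for_kind(
        cls, term: str, kind: TrajectoryKind, incidents_per_year: int
    ) -> "PlantedTerm":
        """Build a term with the canonical shape parameters for ``kind``."""
        d = _KIND_DEFAULTS[kind]
        return cls(
            term=term,
            trajectory_kind=kind,
            base_rate=d["base_frac"] * incidents_per_year,
            slope=d["slope_frac"] * incidents_per_year,
            sigma=d["sigma"],
        )


@dataclass(frozen=True)
class PlantedBlock:
    """A group of terms that co-occur within documents.

    ``within_cooccurrence_prob`` is the probability that a random document
    contains a given *pair* of member terms; ``between_cooccurrence_prob``
    the same for a pair straddling two blocks.  Blocks are realized by
    giving every document a uniformly chosen theme block: members of the
    theme appear with a high per-term probability, members of other blocks
    with a low one, both solved from the requested pair probabilities.
    """

    member_terms: tuple[str, ...]
    within_cooccurrence_prob: float = 0.3
    between_cooccurrence_prob: float = 0.02

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_terms", tuple(self.member_terms))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic corpus."""

    n_years: int = 10
    incidents_per_year: int = 200
    background_vocab_size: int = 400
    planted_terms: tuple[PlantedTerm, ...] = ()
    planted_blocks: tuple[PlantedBlock, ...] = ()
    doc_length_mean: float = 12.0
    first_year: int = 2013
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_terms", tuple(self.planted_terms))
        object.__setattr__(self, "planted_blocks", tuple(self.planted_blocks))
        validate_spec(self)

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.first_year + self.n_years))

    def background_vocab(self) -> list[str]:
        width = len(str(self.background_vocab_size))
        return [f"bg{i:0{width}d}" for i in range(self.background_vocab_size)]


def validate_spec(spec: SyntheticSpec) -> None:
    """Raise :class:`SpecValidationError` naming the violated invariant."""
    if spec.n_years < 3:
        raise SpecValidationError(
            f"n_years must be >= 3 (acceleration needs >= 2 increments), got {spec.n_years}"
        )
    if spec.incidents_per_year < 1:
        raise SpecValidationError(
            f"incidents_per_year must be >= 1, got {spec.incidents_per_year}"
        )
    if spec.doc_length_mean < 2:
        raise SpecValidationError(
            f"doc_length_mean must be >= 2, got {spec.doc_length_mean}"
        )
    planted_names = [t.term for t in spec.planted_terms] + [
        m for b in spec.planted_blocks for m in b.member_terms
    ]
    if len(set(planted_names)) != len(planted_names):
        raise SpecValidationError("planted term names must be unique across terms and blocks")
    background = set(spec.background_vocab())
    clash = background.intersection(planted_names)
    if clash:
        raise SpecValidationError(
            f"planted terms collide with background vocabulary: {sorted(clash)[:5]}"
        )
    for t in spec.planted_terms:
        if t.base_rate < 0:
            raise SpecValidationError(f"base_rate must be >= 0 for {t.term!r}")
        if t.sigma < 0:
            raise SpecValidationError(f"sigma must be >= 0 for {t.term!r}")
    n_blocks = len(spec.planted_blocks)
    for b in spec.planted_blocks:
        if len(b.member_terms) < 2:
            raise SpecValidationError("planted blocks need >= 2 member terms")
        if not (0 <= b.between_cooccurrence_prob < b.within_cooccurrence_prob <= 1):
            raise SpecValidationError(
                "within_cooccurrence_prob must exceed between_cooccurrence_prob "
                f"(got within={b.within_cooccurrence_prob}, between={b.between_cooccurrence_prob})"
            )
        if n_blocks and b.within_cooccurrence_prob > 1.0 / n_blocks:
            raise SpecValidationError(
                f"within_cooccurrence_prob <= 1/n_blocks required "
                f"(got {b.within_cooccurrence_prob} with {n_blocks} blocks)"
            )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _block_member_probs(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (p_in, p_out): member-inclusion probabilities given the
    document's theme is / is not the member's block.

    Solved from the requested pairwise co-occurrence probabilities under
    the uniform-theme model: within = p_in^2 / K and
    between = (2/K) p_in p_out + ((K-2)/K) p_out^2 for K blocks.
    """
    k = len(spec.planted_blocks)
    p_in = np.zeros(k)
    p_out = np.zeros(k)
    for i, b in enumerate(spec.planted_blocks):
        p_in[i] = min(1.0, math.sqrt(k * b.within_cooccurrence_prob))
        a = (k - 2) / k
        bb = 2.0 * p_in[i] / k
        c = -b.between_cooccurrence_prob
        if abs(a) < 1e-12:
            p_out[i] = -c / bb if bb > 0 else 0.0
        else:
            p_out[i] = (-bb + math.sqrt(bb * bb - 4 * a * c)) / (2 * a)
        p_out[i] = min(1.0, max(0.0, p_out[i]))
    return p_in, p_out


def expected_yearly_rate(term: PlantedTerm, spec: SyntheticSpec) -> np.ndarray:
    """Expected documents/year containing ``term``, before the year effect."""
    t = np.arange(spec.n_years, dtype=float)
    mid = (spec.n_years - 1) / 2.0
    rate = term.base_rate + term.slope * (t - mid)
    return np.clip(rate, 0.0, spec.incidents_per_year)


def _year_multipliers(term_idx: int, spec: SyntheticSpec) -> np.ndarray:
    """Mean-one lognormal year effects for one planted term (deterministic)."""
    term = spec.planted_terms[term_idx]
    rng = np.random.default_rng([spec.seed, 7919, term_idx])
    z = rng.standard_normal(spec.n_years)
    return np.exp(term.sigma * z - term.sigma**2 / 2.0)


def generate_corpus(spec: SyntheticSpec) -> list[IncidentRecord]:
    """Generate the corpus described by ``spec``.

    Returns ``n_years * incidents_per_year`` records.  Each document is a
    space-joined bag of tokens: a Poisson-length background draw from the
    Zipf vocabulary, planted terms included by Bernoulli draws at their
    yearly rate, and block members included according to the document's
    theme block.  Identical spec + seed yields byte-identical output.
    """
    validate_spec(spec)
    vocab = np.array(spec.background_vocab())
    ranks = np.arange(1, spec.background_vocab_size + 1, dtype=float)
    zipf_p = ranks**-spec.zipf_exponent
    zipf_p /= zipf_p.sum()

    n_blocks = len(spec.planted_blocks)
    p_in, p_out = _block_member_probs(spec) if n_blocks else (None, None)

    # presence probability per planted term and year, with the volatile
    # lognormal year effect applied on top of the trend
    n_planted = len(spec.planted_terms)
    presence = np.zeros((n_planted, spec.n_years))
    for i, term in enumerate(spec.planted_terms):
        rate = expected_yearly_rate(term, spec) * _year_multipliers(i, spec)
        presence[i] = np.clip(rate / spec.incidents_per_year, 0.0, 1.0)

    records: list[IncidentRecord] = []
    for yi, year in enumerate(spec.years):
        rng = np.random.default_rng([spec.seed, yi])
        n_docs = spec.incidents_per_year
        lengths = np.maximum(2, rng.poisson(spec.doc_length_mean, size=n_docs))
        planted_hits = (
            rng.random((n_docs, n_planted)) < presence[:, yi]
            if n_planted
            else np.zeros((n_docs, 0), dtype=bool)
        )
        themes = rng.integers(0, n_blocks, size=n_docs) if n_blocks else None
        block_draws = rng.random((n_docs, sum(len(b.member_terms) for b in spec.planted_blocks)))
        for d in range(n_docs):
            tokens = list(vocab[rng.choice(spec.background_vocab_size, size=lengths[d], p=zipf_p)])
            for i in np.flatnonzero(planted_hits[d]):
                tokens.append(spec.planted_terms[i].term)
            col = 0
            for bi, block in enumerate(spec.planted_blocks):
                p = p_in[bi] if themes[d] == bi else p_out[bi]
                for m in block.member_terms:
                    if block_draws[d, col] < p:
                        tokens.append(m)
                    col += 1
            rng.shuffle(tokens)
            records.append(
                IncidentRecord(id=f"{year}-{d:05d}", year=year, text=" ".join(tokens))
            )
    return records


def ground_truth(spec: SyntheticSpec) -> dict[str, str]:
    """Intended category per planted term.

    ``flat`` trajectories and block members have no emerging-issue
    signature and map to ``unclassified``.
    """
    validate_spec(spec)
    truth: dict[str, str] = {}
    for t in spec.planted_terms:
        truth[t.term] = t.trajectory_kind if t.trajectory_kind != "flat" else "unclassified"
    for b in spec.planted_blocks:
        for m in b.member_terms:
            truth[m] = "unclassified"
    return truth


def block_membership(spec: SyntheticSpec) -> dict[str, int]:
    """Planted community label per block member term."""
    return {
        m: bi for bi, b in enumerate(spec.planted_blocks) for m in b.member_terms
    }


def make_study_spec(
    seed: int = 0,
    n_years: int = 10,
    incidents_per_year: int = 200,
    n_per_kind: int = 30,
    n_blocks: int = 3,
    block_size: int = 6,
    within_cooccurrence_prob: float = 0.3,
    between_cooccurrence_prob: float = 0.02,
) -> SyntheticSpec:
    """Canonical study-scale spec: a decade of incidents with planted
    trajectories of every kind and recoverable co-occurrence blocks.

    Defaults emulate the study conditions at desk scale: 10 years,
    200 incidents/year, 30 planted terms per trajectory kind, and three
    6-term co-occurrence blocks.
    """
    planted = [
        PlantedTerm.for_kind(f"{kind}{i:02d}", kind, incidents_per_year)
        for kind in ("hazardous", "noteworthy", "diffusion", "flat")
        for i in range(n_per_kind)
    ]
    blocks = [
        PlantedBlock(
            member_terms=tuple(f"blk{bi}m{j}" for j in range(block_size)),
            within_cooccurrence_prob=within_cooccurrence_prob,
            between_cooccurrence_prob=between_cooccurrence_prob,
        )
        for bi in range(n_blocks)
    ]
    return SyntheticSpec(
        n_years=n_years,
        incidents_per_year=incidents_per_year,
        planted_terms=tuple(planted),
        planted_blocks=tuple(blocks),
        seed=seed,
    )


def write_truth_csv(truth: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "category"])
        for term in sorted(truth):
            writer.writerow([term, truth[term]])


def write_corpus(records: list[IncidentRecord], path: str | Path) -> None:
    """Alias for :func:`injurysignals.preprocess.write_records`."""
    write_records(records, path)
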