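"""Emerging-issue categorization of candidate keywords.

Each candidate keyword's yearly document-frequency trajectory is reduced to
three statistics:

* **average frequency** — mean yearly DF over the whole study window
  (absent years count as zero);
* **relative volatility** — the term's yearly-DF standard deviation divided
  by the mean SD over all candidate keywords;
* **average acceleration** — mean year-over-year DF increment accumulated
  from the first study year through the year of the term's last appearance
  (negative for declining terms).

Each statistic is converted to a 1-5 score by quintile of its rank among
the candidates (top 20% -> 5, ..., bottom 20% -> 1), and the scores drive
the category rules:

===========  =============  ============  ==============
category     avg frequency  acceleration  rel volatility
===========  =============  ============  ==============
hazardous    >= 4           >= 4          >= 4
noteworthy   <= 2           >= 3          >= 3
diffusion    >= 4           <= 2          (unconstrained)
===========  =============  ============  ==============

The three rules are mutually exclusive (frequency >= 4 vs <= 2 separates
diffusion/hazardous from noteworthy; acceleration >= 4 vs <= 2 separates
hazardous from diffusion); anything else is ``unclassified``.  Terms naming
times of day, persons or body sites can be excluded by configurable
stoplists before categorization.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .preprocess import ConfigurationError, YearlyTermMatrix

logger = logging.getLogger(__name__)

AccelerationVariant = Literal["first_difference", "second_difference"]
SdVariant = Literal["population", "sample"]


@dataclass(frozen=True)
class TermTrajectory:
    """A term's yearly document-frequency series over the study window."""

    term: str
    freq_by_year: dict[int, int]

    @property
    def first_year(self) -> int | None:
        nz = [y for y, f in self.freq_by_year.items() if f > 0]
        return min(nz) if nz else None

    @property
    def last_year(self) -> int | None:
        nz = [y for y, f in self.freq_by_year.items() if f > 0]
        return max(nz) if nz else None

    def series(self, years: Sequence[int]) -> np.ndarray:
        """Zero-filled frequency series over ``years`` (ascending)."""
        return np.array([self.freq_by_year.get(y, 0) for y in years], dtype=float)


@dataclass(frozen=True)
class KeywordAssessment:
    term: str
    avg_freq: float
    avg_accel: float
    rel_volatility: float
    score_freq: int
    score_accel: int
    score_vol: int
    category: str
    excluded: bool = False
    excluded_reason: str = ""


def build_trajectories(
    matrices: Iterable[YearlyTermMatrix], terms: Iterable[str]
) -> list[TermTrajectory]:
    """Yearly DF trajectories for ``terms`` from per-year matrices."""
    matrices = list(matrices)
    out = []
    for term in terms:
        freq = {
            m.year: len(m.term_in_doc_count.get(term, {}))
            for m in matrices
        }
        out.append(TermTrajectory(term=term, freq_by_year=freq))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def average_frequency(traj: TermTrajectory, n_years: int) -> float:
    """Mean yearly DF over all ``n_years`` study years (absent years = 0)."""
    if n_years < 1:
        raise ConfigurationError(f"n_years must be >= 1, got {n_years}")
    return sum(traj.freq_by_year.values()) / n_years


def trajectory_sd(
    traj: TermTrajectory, years: Sequence[int], variant: SdVariant = "population"
) -> float:
    """Standard deviation of the zero-filled yearly DF series."""
    s = traj.series(years)
    ddof = 0 if variant == "population" else 1
    if len(s) <= ddof:
        return 0.0
    return float(np.std(s, ddof=ddof))


def relative_volatility(
    traj: TermTrajectory,
    all_sds: Sequence[float],
    years: Sequence[int],
    variant: SdVariant = "population",
) -> float:
    """Term SD over the mean SD of all candidate terms.

    Normalizing by the candidate-pool mean SD compensates for vocabulary
    growth over time: volatility is judged relative to the corpus, not in
    absolute document counts.
    """
    if len(all_sds) == 0:
        raise ConfigurationError("relative_volatility requires a non-empty SD pool")
    denom = float(np.mean(all_sds))
    if denom <= 0:
        raise ConfigurationError(
            "degenerate corpus: every candidate trajectory is constant (mean SD = 0)"
        )
    return trajectory_sd(traj, years, variant) / denom


def average_acceleration(
    traj: TermTrajectory,
    years: Sequence[int],
    variant: AccelerationVariant = "first_difference",
) -> float:
    """Mean year-over-year DF increment through the last year of appearance.

    Increments are accumulated from the first study year up to the term's
    last nonzero year, so a term that vanished mid-study is not diluted by
    trailing zeros.  The default treats the increment of raw frequency as
    the "acceleration of appearance" (velocity-style); the
    ``second_difference`` variant averages increments of the increments.
    Spans shorter than two years yield 0.0 (logged).
    """
    years = sorted(years)
    last = traj.last_year
    if last is None:
        return 0.0
    window = [y for y in years if y <= last]
    if len(window) < 2:
        logger.debug("term %r spans < 2 years; acceleration set to 0", traj.term)
        return 0.0
    s = traj.series(window)
    diffs = np.diff(s)
    if variant == "second_difference":
        if len(diffs) < 2:
            logger.debug("term %r: < 2 increments; second difference set to 0", traj.term)
            return 0.0
        diffs = np.diff(diffs)
    elif variant != "first_difference":
        raise ConfigurationError(f"unknown acceleration variant {variant!r}")
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Quintile scores and category rules
# ---------------------------------------------------------------------------


def rank_scores(values: Sequence[float], higher_is_better: bool = True) -> list[int]:
    """Map each value to a 1-5 score by quintile of its percentile rank.

    With distinct values the five bands differ in size by at most one.
    Ties share the score of their mean percentile rank (so an all-equal
    column maps to the middle score 3), making the banding independent of
    input order.
    """
    if len(values) < 5:
        raise ConfigurationError(
            f"rank_scores needs >= 5 values to form quintiles, got {len(values)}"
        )
    arr = np.asarray(values, dtype=float)
    ranks = rankdata(arr if higher_is_better else -arr, method="average")
    n = len(arr)
    return [int(math.ceil(5.0 * r / n)) for r in ranks]


def categorize_scores(score_freq: int, score_accel: int, score_vol: int) -> str:
    """Apply the category rules to one score triple."""
    for s in (score_freq, score_accel, score_vol):
        if not 1 <= s <= 5:
            raise ConfigurationError(f"scores must lie in 1..5, got {s}")
    if score_freq >= 4 and score_accel >= 4 and score_vol >= 4:
        return "hazardous"
    if score_freq <= 2 and score_accel >= 3 and score_vol >= 3:
        return "noteworthy"
    if score_freq >= 4 and score_accel <= 2:
        return "diffusion"
    return "unclassified"


@dataclass(frozen=True)
class Stoplist:
    """Named exclusion lists for terms useless for narrowing injury types."""

    time: frozenset[str] = frozenset()
    person: frozenset[str] = frozenset()
    body_site: frozenset[str] = frozenset()

    @classmethod
    def from_dict(cls, d: dict) -> "Stoplist":
        return cls(
            time=frozenset(d.get("time", ())),
            person=frozenset(d.get("person", ())),
            body_site=frozenset(d.get("body_site", ())),
        )

    def reason_for(self, term: str) -> str:
        if term in self.time:
            return "time"
        if term in self.person:
            return "person"
        if term in self.body_site:
            return "body_site"
        return ""


def apply_stoplist(
    assessments: Iterable[KeywordAssessment], stoplist: Stoplist
) -> list[KeywordAssessment]:
    """Flag assessments whose term appears in a stoplist class.

    Excluded terms keep their metric values but lose their category (an
    excluded term is never reported as an emerging issue).
    """
    out = []
    n_excluded = 0
    for a in assessments:
        reason = stoplist.reason_for(a.term)
        if reason:
            out.append(replace(a, excluded=True, excluded_reason=reason, category="unclassified"))
            n_excluded += 1
        else:
            out.append(a)
    if n_excluded:
        logger.info("stoplist excluded %d terms", n_excluded)
    return out


def assess_keywords(
    trajectories: Iterable[TermTrajectory],
    study_years: Sequence[int],
    stoplist: Stoplist | None = None,
    acceleration_variant: AccelerationVariant = "first_difference",
    sd_variant: SdVariant = "population",
) -> list[KeywordAssessment]:
    """Full categorization of a candidate-keyword pool.

    Scores are banded over the whole pool before stoplist exclusion, so
    removing a noise term does not shift the quintile boundaries of the
    remaining ones.
    """
    trajectories = list(trajectories)
    years = sorted(study_years)
    n_years = len(years)
    sds = [trajectory_sd(t, years, sd_variant) for t in trajectories]
    avg_freqs = [average_frequency(t, n_years) for t in trajectories]
    accels = [average_acceleration(t, years, acceleration_variant) for t in trajectories]
    vols = [relative_volatility(t, sds, years, sd_variant) for t in trajectories]
    s_freq = rank_scores(avg_freqs)
    s_accel = rank_scores(accels)
    s_vol = rank_scores(vols)
    out = [
        KeywordAssessment(
            term=t.term,
            avg_freq=avg_freqs[i],
            avg_accel=accels[i],
            rel_volatility=vols[i],
            score_freq=s_freq[i],
            score_accel=s_accel[i],
            score_vol=s_vol[i],
            category=categorize_scores(s_freq[i], s_accel[i], s_vol[i]),
        )
        for i, t in enumerate(trajectories)
    ]
    if stoplist is not None:
        out = apply_stoplist(out, stoplist)
    return out


def write_assessments(assessments: Iterable[KeywordAssessment], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["term", "avg_freq", "avg_accel", "rel_volatility",
             "score_freq", "score_accel", "score_vol", "category", "excluded_reason"]
        )
        for a in sorted(assessments, key=lambda a: a.term):
            writer.writerow(
                [a.term, f"{a.avg_freq:.4f}", f"{a.avg_accel:.4f}",
                 f"{a.rel_volatility:.4f}", a.score_freq, a.score_accel,
                 a.score_vol, a.category, a.excluded_reason]
            )


def write_category_summary(
    assessments: Iterable[KeywordAssessment], path: str | Path, n_representative: int = 7
) -> None:
    """Per-category summary: N, metric means, representative terms
    (highest average frequency first)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[KeywordAssessment]] = {}
    for a in assessments:
        if not a.excluded:
            groups.setdefault(a.category, []).append(a)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["category", "n_terms", "mean_avg_freq", "mean_avg_accel",
             "mean_rel_volatility", "representative_terms"]
        )
        for cat in ("hazardous", "noteworthy", "diffusion", "unclassified"):
            members = groups.get(cat, [])
            if not members:
                writer.writerow([cat, 0, "", "", "", ""])
                continue
            reps = sorted(members, key=lambda a: (-a.avg_freq, a.term))[:n_representative]
            writer.writerow(
                [cat, len(members),
                 f"{np.mean([a.avg_freq for a in members]):.4f}",
                 f"{np.mean([a.avg_accel for a in members]):.4f}",
                 f"{np.mean([a.rel_volatility for a in members]):.4f}",
                 "; ".join(a.term for a in reps)]
            )
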