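"""Phi-coefficient semantic network around focal (ego) keywords.

Incidents mentioning at least one focal keyword form a sub-corpus; within
it, every pair of sufficiently supported terms gets a phi coefficient from
its 2x2 co-occurrence contingency table

    phi = (AD - BC) / sqrt((A+B)(C+D)(A+C)(B+D))

where A counts documents containing both terms, B/C exactly one, and D
neither — identically the Pearson correlation of the two binary presence
indicators.  The network is reduced to the 1.5-degree ego network (egos,
their direct neighbors, and all links among the kept nodes), weak links
below a phi threshold are pruned, and communities are found by modularity
maximization (exact enumeration on tiny graphs, seeded Louvain otherwise).

Link-strength interpretation bands: phi in [0.05, 0.10) weak,
[0.10, 0.15) moderate, [0.15, 0.25) strong, >= 0.25 very strong.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import (
    ConfigurationError,
    IncidentRecord,
    PipelineError,
    Tokenizer,
    get_tokenizer,
)

logger = logging.getLogger(__name__)

FilterOrder = Literal["ego_then_phi", "phi_then_ego"]

STRENGTH_BANDS = (
    (0.05, 0.10, "weak"),
    (0.10, 0.15, "moderate"),
    (0.15, 0.25, "strong"),
    (0.25, math.inf, "very_strong"),
)


class UndefinedCorrelationError(ValueError):
    """Phi is undefined: one of the four contingency marginals is zero."""


@dataclass(frozen=True)
class ContingencyPair:
    """2x2 co-occurrence table for a term pair over a document set."""

    term1: str
    term2: str
    a: int  # docs containing both
    b: int  # docs with term1 only
    c: int  # docs with term2 only
    d: int  # docs with neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n_docs(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SemanticGraph:
    """Term graph with phi-weighted edges and a designated ego set."""

    graph: nx.Graph
    egos: frozenset[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# Sub-corpus selection and incidence
# ---------------------------------------------------------------------------


def select_subcorpus(
    records: Iterable[IncidentRecord],
    hazardous_terms: Sequence[str],
    tokenizer: Tokenizer | str = "default",
) -> list[IncidentRecord]:
    """Records whose tokenized narrative contains >= 1 focal term.

    A record mentioning several focal terms is selected once.  Raises
    :class:`PipelineError` when no record matches (focal terms absent from
    the corpus).
    """
    if not hazardous_terms:
        raise PipelineError("select_subcorpus requires a non-empty focal term list")
    fn = get_tokenizer(tokenizer) if isinstance(tokenizer, str) else tokenizer
    focal = set(hazardous_terms)
    out = [r for r in records if focal.intersection(fn(r.text))]
    if not out:
        raise PipelineError(
            "no records contain any focal term; egos absent from corpus"
        )
    logger.info("sub-corpus: %d records contain >= 1 of %d focal terms",
                len(out), len(focal))
    return out


def binary_incidence(
    records: Iterable[IncidentRecord],
    tokenizer: Tokenizer | str = "default",
    min_df: int = 10,
) -> tuple[list[str], np.ndarray]:
    """Pooled binary document-term incidence over a record set.

    Terms with document frequency below ``min_df`` in the pooled set are
    dropped (the support re-application on the sub-corpus).  Returns the
    sorted retained vocabulary and a (docs x terms) boolean matrix.
    """
    fn = get_tokenizer(tokenizer) if isinstance(tokenizer, str) else tokenizer
    doc_sets = [set(fn(r.text)) for r in records]
    doc_sets = [s for s in doc_sets if s]
    if not doc_sets:
        raise PipelineError("empty sub-corpus after tokenization")
    df: dict[str, int] = {}
    for s in doc_sets:
        for t in s:
            df[t] = df.get(t, 0) + 1
    vocab = sorted(t for t, n in df.items() if n >= min_df)
    index = {t: j for j, t in enumerate(vocab)}
    mat = np.zeros((len(doc_sets), len(vocab)), dtype=bool)
    for i, s in enumerate(doc_sets):
        for t in s:
            j = index.get(t)
            if j is not None:
                mat[i, j] = True
    return vocab, mat


# ---------------------------------------------------------------------------
# Phi coefficient
# ---------------------------------------------------------------------------


def phi(pair: ContingencyPair) -> float:
    """Phi coefficient of a 2x2 contingency table, in [-1, 1]."""
    a, b, c, d = float(pair.a), float(pair.b), float(pair.c), float(pair.d)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        raise UndefinedCorrelationError(
            f"zero marginal in contingency table for ({pair.term1!r}, {pair.term2!r})"
        )
    return (a * d - b * c) / math.sqrt(denom)


def classify_strength(value: float) -> str:
    """Interpretation band for a retained (phi >= 0.05) link."""
    for lo, hi, band in STRENGTH_BANDS:
        if lo <= value < hi:
            return band
    raise ValueError(f"phi {value} below the 0.05 retention floor has no band")


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_graph(
    vocab: Sequence[str],
    incidence: np.ndarray,
    egos: Sequence[str],
    phi_threshold: float = 0.05,
    min_cooccurrence: int = 10,
    filter_order: FilterOrder = "ego_then_phi",
) -> SemanticGraph:
    """Build the phi-filtered ego network from a binary incidence matrix.

    Pipeline: (1) compute phi for every term pair whose co-occurrence count
    (documents containing both) reaches ``min_cooccurrence`` and whose
    marginals are non-degenerate; (2) extract the 1.5-degree ego network
    (egos + direct neighbors + all links among them); (3) drop links with
    phi below ``phi_threshold``; (4) remove non-ego nodes left isolated.
    ``filter_order="phi_then_ego"`` swaps steps (2) and (3).
    """
    if phi_threshold < 0 or min_cooccurrence < 0:
        raise ConfigurationError("thresholds must be >= 0")
    ego_set = frozenset(e for e in egos if e in set(vocab))
    if not ego_set:
        raise PipelineError("no ego term present in the sub-corpus vocabulary")

    n_docs = incidence.shape[0]
    counts = incidence.astype(np.int64)
    cooc = counts.T @ counts  # a-cell for every pair; diagonal = DF
    df = np.diag(cooc)

    full = nx.Graph()
    full.add_nodes_from(vocab)
    skipped_degenerate = 0
    ii, jj = np.nonzero(np.triu(cooc >= min_cooccurrence, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        a = int(cooc[i, j])
        b = int(df[i] - a)
        c = int(df[j] - a)
        d = int(n_docs - a - b - c)
        pair = ContingencyPair(vocab[i], vocab[j], a, b, c, d)
        try:
            value = phi(pair)
        except UndefinedCorrelationError:
            skipped_degenerate += 1
            continue
        full.add_edge(vocab[i], vocab[j], phi=value, cooccurrence=a)
    if skipped_degenerate:
        logger.info("skipped %d pairs with degenerate marginals", skipped_degenerate)

    def extract_ego(g: nx.Graph) -> nx.Graph:
        kept = set(ego_set)
        for e in ego_set:
            kept.update(g.neighbors(e))
        return g.subgraph(kept).copy()

    def prune_phi(g: nx.Graph) -> nx.Graph:
        weak = [(u, v) for u, v, w in g.edges(data="phi") if w < phi_threshold]
        g.remove_edges_from(weak)
        return g

    if filter_order == "ego_then_phi":
        g = prune_phi(extract_ego(full))
    elif filter_order == "phi_then_ego":
        g = extract_ego(prune_phi(full))
    else:
        raise ConfigurationError(f"unknown filter_order {filter_order!r}")

    isolated = [n for n in g.nodes if g.degree(n) == 0 and n not in ego_set]
    g.remove_nodes_from(isolated)

    # rebuild in sorted order so serialized output is deterministic
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(g.nodes))
    ordered.add_edges_from(
        (u, v, g.edges[u, v]) for u, v in sorted(tuple(sorted(e)) for e in g.edges)
    )
    for n in ordered.nodes:
        ordered.nodes[n]["is_ego"] = n in ego_set
    return SemanticGraph(graph=ordered, egos=ego_set)


# ---------------------------------------------------------------------------
# Community detection
# ---------------------------------------------------------------------------


def _partitions(items: Sequence[str]):
    """All set partitions of ``items`` (first element anchored per cell)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def _exact_partition(
    g: nx.Graph, weight: str | None, resolution: float
) -> tuple[list[set[str]], float]:
    """Exhaustive modularity maximization; ties broken toward the
    lexicographically smallest canonical partition."""
    nodes = sorted(g.nodes)
    best: tuple[float, list[list[str]]] | None = None
    for part in _partitions(nodes):
        q = nx.community.modularity(
            g, [set(c) for c in part], weight=weight, resolution=resolution
        )
        canon = sorted(sorted(c) for c in part)
        if best is None or q > best[0] + 1e-12 or (
            abs(q - best[0]) <= 1e-12 and canon < best[1]
        ):
            best = (q, canon)
    assert best is not None
    return [set(c) for c in best[1]], best[0]


def louvain_communities(
    sg: SemanticGraph | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    weight: str | None = "phi",
    exact_max_nodes: int = 8,
) -> CommunityPartition:
    """Modularity-maximizing partition of the semantic graph.

    Uses seeded Louvain; graphs with at most ``exact_max_nodes`` nodes are
    instead solved by exhaustive enumeration over all partitions, which is
    cheap at that size and makes results on small graphs exactly optimal
    and tie-stable.  Edge weights default to the phi values (nonnegative
    after filtering); ``weight=None`` treats links as unweighted.
    """
    g = sg.graph if isinstance(sg, SemanticGraph) else sg
    nodes = sorted(g.nodes)
    if not nodes:
        raise PipelineError("cannot partition an empty graph")
    if g.number_of_edges() == 0:
        return CommunityPartition(
            assignment={n: i for i, n in enumerate(nodes)}, modularity=0.0
        )
    if g.number_of_nodes() <= exact_max_nodes:
        communities, q = _exact_partition(g, weight, resolution)
    else:
        communities = nx.community.louvain_communities(
            g, weight=weight, resolution=resolution, seed=seed
        )
        q = nx.community.modularity(g, communities, weight=weight, resolution=resolution)
    # stable community ids: order by smallest member term
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    return CommunityPartition(assignment=assignment, modularity=float(q))


def singleton_modularity(sg: SemanticGraph | nx.Graph, weight: str | None = "phi") -> float:
    g = sg.graph if isinstance(sg, SemanticGraph) else sg
    if g.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(g, [{n} for n in g.nodes], weight=weight)


# ---------------------------------------------------------------------------
# Reporting and serialization
# ---------------------------------------------------------------------------


def degree_report(
    sg: SemanticGraph, partition: CommunityPartition
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node and per-community tables.

    Nodes are sorted by degree descending then term ascending; the
    community table lists each community's size and members.
    """
    g = sg.graph
    nodes = pd.DataFrame(
        {
            "term": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "community": [partition.assignment[n] for n in g.nodes],
            "is_ego": [n in sg.egos for n in g.nodes],
        }
    ).sort_values(["degree", "term"], ascending=[False, True], ignore_index=True)
    comm = (
        nodes.groupby("community")
        .agg(n_nodes=("term", "size"), members=("term", lambda s: "; ".join(sorted(s))))
        .reset_index()
        .sort_values("community", ignore_index=True)
    )
    return nodes, comm


def write_edge_list(sg: SemanticGraph, path: str | Path) -> None:
    """Edge-list CSV: term1, term2, phi, cooccurrence, strength band."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term1", "term2", "phi", "cooccurrence", "band"])
        for u, v in sorted(tuple(sorted(e)) for e in sg.graph.edges):
            data = sg.graph.edges[u, v]
            band = classify_strength(data["phi"]) if data["phi"] >= 0.05 else ""
            writer.writerow([u, v, f"{data['phi']:.6f}", data["cooccurrence"], band])


def write_graphml(sg: SemanticGraph, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(sg.graph, path)


def write_communities(
    nodes_table: pd.DataFrame, path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nodes_table.to_csv(path, index=False)


def write_summary(
    sg: SemanticGraph, partition: CommunityPartition, path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary = {
        "n_nodes": sg.n_nodes,
        "n_edges": sg.n_edges,
        "n_egos": len(sg.egos),
        "modularity": round(partition.modularity, 6),
        "n_communities": partition.n_communities,
    }
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
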