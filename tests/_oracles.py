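"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (two-loop recomputations, indicator
expansion, exhaustive partition search) and shares no code with the
implementation under test.
"""

import math

import numpy as np


def naive_tfidf_oracle(records):
    """Two-loop TF-IDF recomputation straight from the narrative texts."""
    docs = [r.text.split() for r in records]
    n = len(docs)
    vocab = sorted({t for d in docs for t in d})
    out = {}
    for term in vocab:
        tf_max, df = 0.0, 0
        for d in docs:
            if term in d:
                df += 1
                tf_max = max(tf_max, d.count(term) / len(d))
        out[term] = tf_max * math.log(n / df)
    return out


def pearson_phi_oracle(a, b, c, d):
    """Pearson correlation of expanded binary indicator vectors."""
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def modularity_oracle(g, partition, weight="phi"):
    """Explicit-formula modularity of a node->community assignment."""
    m2 = sum(d.get(weight, 1.0) for _, _, d in g.edges(data=True)) * 2.0
    deg = {
        n: sum(g.edges[n, nbr].get(weight, 1.0) for nbr in g.neighbors(n))
        for n in g.nodes
    }
    q = 0.0
    for u in g.nodes:
        for v in g.nodes:
            if partition[u] != partition[v]:
                continue
            a_uv = g.edges[u, v].get(weight, 1.0) if g.has_edge(u, v) else 0.0
            q += a_uv - deg[u] * deg[v] / m2
    return q / m2


def set_partitions(items):
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1:]
        yield part + [[head]]


def brute_force_best_partition(g, weight="phi"):
    """Exhaustive modularity maximization over all set partitions."""
    best_q, best = -math.inf, None
    for cells in set_partitions(list(g.nodes)):
        partition = {n: i for i, cell in enumerate(cells) for n in cell}
        q = modularity_oracle(g, partition, weight)
        if q > best_q + 1e-12:
            best_q, best = q, partition
    return best, best_q
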