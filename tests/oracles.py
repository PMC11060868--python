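"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: modularity is
recomputed from a dense weight matrix over explicitly enumerated set
partitions, and graphs are drawn from a planted-partition model (the graph
family community detection is defined on).
"""

import numpy as np

from rduplex.clustering import GapGraph


def partitions(xs):
    """All set partitions of a list (restricted-growth enumeration)."""
    if not xs:
        yield []
        return
    first, rest = xs[0], xs[1:]
    for p in partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1 :]
        yield [[first]] + p


def exhaustive_best_partition(graph: GapGraph):
    """(best partition, best Q, second-best Q) by full enumeration."""
    n = len(graph.vertices)
    idx = {v: i for i, v in enumerate(graph.vertices)}
    w = np.zeros((n, n))
    for (u, v), wt in zip(graph.edges, graph.weights):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = wt
    deg = w.sum(axis=1)
    tot = w.sum() / 2.0
    best_q, second_q, best_p = -2.0, -2.0, None
    for p in partitions(list(range(n))):
        q = 0.0
        for c in p:
            ci = np.asarray(c)
            q += w[np.ix_(ci, ci)].sum() / (2.0 * tot) - (
                deg[ci].sum() / (2.0 * tot)
            ) ** 2
        if q > best_q:
            second_q, best_q = best_q, q
            best_p = p
        elif q > second_q:
            second_q = q
    best = [{graph.vertices[i] for i in c} for c in best_p]
    return best, best_q, second_q


def planted_graph(rng: np.random.Generator) -> GapGraph:
    """Random weighted graph with planted community structure (4-8 vertices)."""
    n = int(rng.integers(4, 9))
    k = int(rng.integers(1, min(3, n // 2) + 1))
    labels = rng.integers(0, k, size=n)
    verts = [f"v{i}" for i in range(n)]
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            same = labels[i] == labels[j]
            if rng.random() < (0.9 if same else 0.2):
                edges.append((verts[i], verts[j]))
                weights.append(
                    float(rng.integers(6, 11) if same else rng.integers(1, 4)) / 10.0
                )
    return GapGraph(verts, edges, weights)


def walktrap_oracle_suite(seed: int, n_graphs: int = 200, margin: float = 0.05):
    """Yield (graph, oracle partition) for graphs whose maximum-modularity
    partition is unique with the given margin."""
    rng = np.random.default_rng(seed)
    produced = 0
    while produced < n_graphs:
        g = planted_graph(rng)
        if g.n_edges == 0:
            continue
        best, best_q, second_q = exhaustive_best_partition(g)
        if best_q - second_q <= margin:
            continue
        produced += 1
        yield g, best
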