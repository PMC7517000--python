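"""Independent brute-force oracles used across the test modules.

Everything here is deliberately naive (exhaustive enumeration, all-pairs
BFS through networkx) and never shares code with the implementation it
checks.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx
import numpy as np


def brute_avg_path(g: nx.Graph) -> float:
    """All-pairs BFS average shortest path length."""
    return nx.average_shortest_path_length(g)


def brute_diameter(g: nx.Graph) -> int:
    return nx.diameter(g)


def expected_qc(g: nx.Graph, r: int) -> float:
    """Exact E[Qc(r)] over all uniformly random seed sequences.

    Recursion over covered-node bitmasks: from a covered set, the next
    seed is uniform among uncovered nodes and absorbs the radius-(r-1)
    ball around it.  Exact for graphs small enough to enumerate
    (<= ~20 nodes).
    """
    nodes = sorted(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    balls = [
        sum(1 << index[v] for v in nodes if dist[u].get(v, n + 1) <= r - 1)
        for u in nodes
    ]
    full = (1 << n) - 1

    @lru_cache(maxsize=None)
    def rec(covered: int) -> float:
        if covered == full:
            return 0.0
        uncovered = [i for i in range(n) if not (covered >> i) & 1]
        return 1.0 + sum(rec(covered | balls[i]) for i in uncovered) / len(uncovered)

    val = rec(0)
    rec.cache_clear()
    return val


def random_tree(n: int, rng: np.random.Generator) -> nx.Graph:
    """Uniform random labelled tree (random attachment construction)."""
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        g.add_edge(v, int(rng.integers(0, v)))
    return g
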