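"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately avoids the code path it checks: betweenness by
explicit enumeration of all shortest paths, the hypergeometric tail by
exact rational arithmetic, and BH by the literal step-up definition.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


def brute_force_betweenness(g: nx.Graph, normalized: bool = True) -> dict:
    """Betweenness by enumerating every shortest path between every pair.

    For each unordered pair (s, t), all shortest paths are listed
    (nx.all_shortest_paths is itself BFS-based but is used only to
    enumerate, not to count dependencies); each interior vertex of each
    path receives credit 1/#paths.
    """
    bc = dict.fromkeys(g, 0.0)
    for s, t in combinations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for interior in path[1:-1]:
                bc[interior] += 1.0 / len(paths)
    n = g.number_of_nodes()
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0 if n > 2 else np.inf
        return {v: b / denom for v, b in bc.items()}
    return bc


def interior_incidence_count(g: nx.Graph) -> float:
    """Total fractional count of shortest-path interior incidences, i.e.
    the sum of raw (unnormalized) betweenness over all nodes."""
    return sum(brute_force_betweenness(g, normalized=False).values())


def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q
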