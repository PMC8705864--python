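"""Hub-gene selection by betweenness centrality.

The filtered DEG network is decomposed into connected components; the
component with the largest unweighted diameter is taken as the "main"
network; normalized betweenness centrality (Brandes' algorithm) is
computed within it, z-scored against the component's own distribution,
and nodes with z > 1.96 (strict, upper tail) are the key/hub genes.
Their first-neighbor subnetwork is the union of the key nodes and every
node adjacent to one of them, with all internal edges retained.

Betweenness is normalized by (n-1)(n-2)/2 — the number of ordered source
/target pairs excluding the node itself, halved for an undirected graph —
so values lie in [0, 1] and match Cytoscape NetworkAnalyzer's convention.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ComponentSummary",
    "HubSelection",
    "connected_components",
    "diameter",
    "select_main_component",
    "betweenness",
    "zscores",
    "zscore_select",
    "neighbor_subnetwork",
]

DEFAULT_Z_CUTOFF = 1.96


@dataclass(frozen=True)
class ComponentSummary:
    component_id: int
    nodes: frozenset = field(repr=False)
    n_nodes: int
    diameter: int


@dataclass(frozen=True)
class HubSelection:
    key_nodes: tuple  # descending betweenness
    neighbor_nodes: frozenset
    subnetwork: nx.Graph = field(repr=False)


def connected_components(g: nx.Graph) -> list[ComponentSummary]:
    """Maximal connected node sets with their diameters, largest first."""
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(map(str, c))))
    return [
        ComponentSummary(
            component_id=i, nodes=c, n_nodes=len(c), diameter=diameter(g.subgraph(c))
        )
        for i, c in enumerate(comps)
    ]


def diameter(component: nx.Graph) -> int:
    """Max over node pairs of unweighted shortest-path length."""
    if component.number_of_nodes() == 0:
        raise ValueError("empty graph has no diameter")
    if not nx.is_connected(component):
        raise ValueError("diameter requires a connected component")
    if component.number_of_nodes() == 1:
        return 0
    return int(nx.diameter(component))


def select_main_component(g: nx.Graph) -> nx.Graph:
    """Component with the largest diameter.

    Ties go to the larger component, then to the component containing the
    smallest node id, so the choice is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot select a component of an empty network")
    best = min(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-diameter(g.subgraph(c)), -len(c), min(map(str, c))),
    )
    return g.subgraph(best).copy()


def betweenness(component: nx.Graph, normalized: bool = True) -> dict:
    """Brandes betweenness centrality, endpoints excluded.

    Single-source shortest-path counts are accumulated into pair
    dependencies; with multiple shortest paths each carries fractional
    credit.  Undirected: the two-pass double count is halved.  Normalized
    by (n-1)(n-2)/2 when requested.
    """
    bc = dict.fromkeys(component, 0.0)
    for s in component:
        stack: list = []
        preds: dict = {v: [] for v in component}
        sigma = dict.fromkeys(component, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in component[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(component, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    n = component.number_of_nodes()
    scale = 0.5  # undirected double count
    if normalized:
        if n > 2:
            scale /= (n - 1) * (n - 2) / 2.0
        else:
            scale = 0.0  # no interior pairs exist
    return {v: b * scale for v, b in bc.items()}


def zscores(values: dict) -> dict:
    """Population z-scores of a per-node value map.

    The component being normalized is treated as the whole population, so
    the population (not sample) standard deviation is used.
    """
    arr = np.asarray(list(values.values()), dtype=float)
    sd = arr.std()  # population sd
    if sd == 0:
        return {v: 0.0 for v in values}
    mean = arr.mean()
    return {v: (b - mean) / sd for v, b in values.items()}


def zscore_select(centrality: dict, cutoff: float = DEFAULT_Z_CUTOFF) -> list:
    """Nodes whose z-scored centrality strictly exceeds ``cutoff``,
    ordered by descending raw centrality (node id breaks exact ties)."""
    if len(centrality) < 2:
        return []
    arr = np.asarray(list(centrality.values()), dtype=float)
    if arr.std() == 0:
        warnings.warn("degenerate centrality distribution (zero spread); no hub selected", stacklevel=2)
        return []
    z = zscores(centrality)
    selected = [v for v in centrality if z[v] > cutoff]
    return sorted(selected, key=lambda v: (-centrality[v], str(v)))


def neighbor_subnetwork(component: nx.Graph, key_nodes) -> HubSelection:
    """First-neighbor subnetwork of the key nodes.

    Neighbor set = union of the key nodes' adjacency sets minus the key
    nodes themselves; the subnetwork is induced on keys + neighbors, so
    every edge among the union is retained.
    """
    key_nodes = list(key_nodes)
    missing = [k for k in key_nodes if k not in component]
    if missing:
        raise ValueError(f"key node(s) absent from component: {missing}")
    neighbors: set = set()
    for k in key_nodes:
        neighbors.update(component[k])
    neighbors -= set(key_nodes)
    sub = component.subgraph(set(key_nodes) | neighbors).copy()
    return HubSelection(
        key_nodes=tuple(key_nodes), neighbor_nodes=frozenset(neighbors), subnetwork=sub
    )
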