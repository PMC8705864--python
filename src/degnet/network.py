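"""Confidence-filtered protein-interaction network over a DEG set.

Reads STRING-style "detailed" edge tables (per-evidence-channel scores
plus a combined score), recombines confidence from a chosen subset of
channels with the naive-Bayes scheme STRING publishes (prior removal,
noisy-OR combination, prior re-addition), filters at a combined-score
threshold (default 0.900, inclusive), induces the subgraph on the DEG
set and drops nodes left with degree zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "EdgeRecord",
    "read_edges",
    "combine_channels",
    "build_network",
    "write_edge_list",
    "write_graphml",
]

STRING_PRIOR = 0.041
DEFAULT_THRESHOLD = 0.900
DEFAULT_CHANNELS = ("experiments", "database")


@dataclass(frozen=True)
class EdgeRecord:
    """Undirected interaction with per-channel confidences in [0, 1]."""

    node1: str
    node2: str
    channel_scores: dict[str, float] = field(repr=False)
    combined: float = 0.0

    def __post_init__(self) -> None:
        if self.node1 == self.node2:
            raise ValueError(f"self-loop on {self.node1!r}")
        for name, s in self.channel_scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"channel {name!r} score {s} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.node1, self.node2) if self.node1 <= self.node2 else (self.node2, self.node1)


def read_edges(path, dialect: str = "milli") -> list[EdgeRecord]:
    """Parse a STRING-detailed edge TSV into records.

    ``milli`` dialect holds integer scores on 0-1000 (divided by 1000 on
    read); ``fraction`` passes scores through.  Duplicate undirected pairs
    are merged keeping the per-channel maximum.
    """
    if dialect not in ("milli", "fraction"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'milli' or 'fraction'")
    df = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2"}
    if not required <= set(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    channels = [c for c in df.columns if c not in ("protein1", "protein2", "combined_score")]
    scale = 1000.0 if dialect == "milli" else 1.0
    merged: dict[tuple[str, str], dict[str, float]] = {}
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        a, b = str(row["protein1"]), str(row["protein2"])
        if a == b:
            raise ValueError(f"line {lineno}: self-loop on {a!r}")
        scores = {}
        for c in channels:
            s = float(row[c]) / scale
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"line {lineno}: channel {c!r} score outside range")
            scores[c] = s
        key = (a, b) if a <= b else (b, a)
        if key in merged:
            for c, s in scores.items():
                merged[key][c] = max(merged[key][c], s)
        else:
            merged[key] = scores
    return [
        EdgeRecord(node1=k[0], node2=k[1], channel_scores=v, combined=0.0)
        for k, v in merged.items()
    ]


def combine_channels(
    channel_scores: dict[str, float],
    channels=DEFAULT_CHANNELS,
    prior: float = STRING_PRIOR,
) -> float:
    """Naive-Bayes recombination of evidence channels.

    Per channel the prior is removed, ``s' = max(0, (s - prior)/(1 -
    prior))``; the channels are combined as a noisy OR, ``1 - prod(1 -
    s')``; the prior is re-added to a nonzero combination.  ``prior=0``
    gives the plain noisy-OR ("simple" mode).
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior must lie in [0, 1), got {prior}")
    missing = [c for c in channels if c not in channel_scores]
    if missing:
        raise ValueError(f"missing evidence channel(s): {missing}")
    remainder = 1.0
    for c in channels:
        s = channel_scores[c]
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel {c!r} score {s} outside [0, 1]")
        s_adj = max(0.0, (s - prior) / (1.0 - prior))
        remainder *= 1.0 - s_adj
    combined_raw = 1.0 - remainder
    if combined_raw <= 0.0:
        return 0.0
    return combined_raw * (1.0 - prior) + prior


def build_network(
    edges: list[EdgeRecord],
    deg_genes: set[str],
    threshold: float = DEFAULT_THRESHOLD,
    channels=DEFAULT_CHANNELS,
    prior: float = STRING_PRIOR,
) -> nx.Graph:
    """Induce the confidence-filtered interaction network on the DEG set.

    Keeps edges whose endpoints are both DEGs and whose recombined score
    is >= ``threshold`` (0.900 passes exactly).  The node set is the set
    of surviving edge endpoints, so degree-0 DEGs are removed.
    """
    if not deg_genes:
        raise ValueError("deg_genes must be nonempty")
    g = nx.Graph()
    for e in edges:
        if e.node1 not in deg_genes or e.node2 not in deg_genes:
            continue
        score = combine_channels(e.channel_scores, channels=channels, prior=prior)
        if score >= threshold:
            a, b = e.key
            if g.has_edge(a, b):
                score = max(score, g[a][b]["combined"])
            g.add_edge(a, b, combined=score)
    if g.number_of_edges() == 0:
        warnings.warn("no edge survived the confidence filter; network is empty", stacklevel=2)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {"protein1": a, "protein2": b, "combined_score": d.get("combined", float("nan"))}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
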