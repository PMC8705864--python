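"""Seeded synthetic inputs with known ground truth.

Generates the three inputs the pipeline consumes — a two-cohort
negative-binomial count matrix with a planted DEG set, a sparse
scale-free interactome with planted high-betweenness hubs, and an
annotation corpus with planted enriched terms — so every downstream
stage can be exercised and scored against a recorded truth with no
external data.

Statistical world (defaults):

* 2000 genes, 8 + 8 samples; baseline means mu_g ~ LogNormal(ln 100, 1)
  — a bulk RNA-seq-like spread from a handful to a few thousand counts;
* NB counts with variance = mu + d mu^2 at d = 0.05 (moderate biological
  replication); 10% of genes differentially expressed at |log2 FC| = 2
  with random sign;
* a preferential-attachment interactome (2 edges/node) whose evidence
  scores are Beta-distributed either well above or well below the 0.9
  confidence threshold; 3 planted hubs, each a DEG star-wired to 15 DEG
  neighbors and chained through DEG bridge nodes so that the planted
  blob is the largest-diameter component of the DEG-induced network;
* 50 annotation terms of 20-40 genes, 5 of which draw 80% of their
  members from the planted DEG set.

All three generators are pure functions of (config, seed); the single
global seed expands to per-stage child seeds by fixed offsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .de import Design
from .network import combine_channels

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_interactome",
    "simulate_annotations",
    "simulate_all",
]

# fixed child-seed offsets (stage-level reproducibility)
_OFFSET_COUNTS = 0
_OFFSET_NETWORK = 1_000_003
_OFFSET_ANNOTATIONS = 2_000_003

CATEGORIES = (
    "apoptosis",
    "brain organization",
    "cell cycle",
    "immune response",
    "oxidative stress",
    "viral replication",
)


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_samples_a: int = 8
    n_samples_b: int = 8
    frac_de: float = 0.10
    lfc_magnitude: float = 2.0
    mean_log_mu: float = math.log(100.0)
    sd_log_mu: float = 1.0
    dispersion: float = 0.05
    n_edges_per_node: int = 2
    n_planted_hubs: int = 3
    n_hub_neighbors: int = 15
    frac_pass: float = 0.5
    n_terms: int = 50
    term_size_range: tuple[int, int] = (20, 40)
    n_enriched_terms: int = 5
    enriched_frac: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        positive = ("n_genes", "n_samples_a", "n_samples_b", "lfc_magnitude",
                    "dispersion", "n_edges_per_node")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        nonneg = ("n_planted_hubs", "n_terms", "n_enriched_terms", "n_hub_neighbors")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("config field 'frac_de' must lie in [0, 1]")
        if 0.0 < self.frac_de and self.frac_de * self.n_genes < 1.0:
            raise ValueError("config field 'frac_de' plants less than one gene")
        if not 0.0 <= self.frac_pass <= 1.0:
            raise ValueError("config field 'frac_pass' must lie in [0, 1]")
        if not 0.0 <= self.enriched_frac <= 1.0:
            raise ValueError("config field 'enriched_frac' must lie in [0, 1]")
        lo, hi = self.term_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ValueError("config field 'term_size_range' must satisfy 0 < min <= max <= n_genes")
        if self.n_terms < self.n_enriched_terms:
            raise ValueError("config field 'n_enriched_terms' exceeds 'n_terms'")
        if self.n_planted_hubs and self.n_hub_neighbors < 10:
            raise ValueError("config field 'n_hub_neighbors' must be >= 10 when hubs are planted")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth sufficient to score every downstream stage."""

    de_genes: dict[str, float] = field(repr=False)  # gene id -> signed log2 effect
    hub_genes: tuple[str, ...] = ()
    enriched_terms: tuple[str, ...] = ()
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "de_genes": self.de_genes,
                    "hub_genes": list(self.hub_genes),
                    "enriched_terms": list(self.enriched_terms),
                    "seed": self.seed,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, Design, SimTruth]:
    """Two-cohort NB count matrix with a planted DEG set.

    Baseline means are LogNormal(mean_log_mu, sd_log_mu); each planted DE
    gene shifts its cohort-B mean by 2**(+/- lfc_magnitude) with a
    uniformly random sign.  Counts are NB with variance mu + d mu^2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _OFFSET_COUNTS)
    genes = _gene_ids(config.n_genes)
    samples_a = [f"A{i + 1:02d}" for i in range(config.n_samples_a)]
    samples_b = [f"B{i + 1:02d}" for i in range(config.n_samples_b)]

    mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, config.n_genes))
    n_de = round(config.frac_de * config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(config.n_genes)
    lfc[de_idx] = signs * config.lfc_magnitude
    mu_b = mu * 2.0**lfc

    d = config.dispersion
    size = 1.0 / d  # NB shape: var = mu + d mu^2

    def draw(means: np.ndarray, n_samples: int) -> np.ndarray:
        p = size / (size + means)
        return rng.negative_binomial(size, p[:, None], size=(config.n_genes, n_samples))

    counts = np.hstack([draw(mu, config.n_samples_a), draw(mu_b, config.n_samples_b)])
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples_a + samples_b)
    design = Design(
        assignments={**{s: "A" for s in samples_a}, **{s: "B" for s in samples_b}},
        cohort_a="A",
        cohort_b="B",
    )
    truth = SimTruth(
        de_genes={genes[i]: float(lfc[i]) for i in sorted(de_idx)},
        hub_genes=(),
        enriched_terms=(),
        seed=config.seed,
    )
    return frame, design, truth


def _passing_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    """Channel scores with mode above 0.9 (pairs recombine above it)."""
    return rng.beta(40.0, 2.0, size=(n, 2))


def _failing_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    """Channel scores with mode well below 0.9."""
    return rng.beta(2.0, 8.0, size=(n, 2))


def simulate_interactome(
    gene_universe: list[str], config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, SimTruth]:
    """Scale-free edge table with planted high-betweenness hubs.

    A preferential-attachment backbone covers the whole gene universe;
    a fraction ``frac_pass`` of backbone edges receives evidence scores
    that survive the 0.9 combined-score filter.  Each planted hub is a DE
    gene star-wired (always-passing edges) to ``n_hub_neighbors`` distinct
    DE neighbors, and consecutive hubs are chained through dedicated DE
    bridge nodes, so the hub blob forms the largest-diameter component of
    the downstream DEG-induced network and each hub lands in the upper
    z > 1.96 betweenness tail.

    Returns the edge table (fraction-scale channel scores plus the
    recombined ``combined_score``) and a truth updated with the hubs.
    """
    config.validate()
    if not gene_universe:
        raise ValueError("gene_universe must be nonempty")
    if len(gene_universe) < config.n_edges_per_node + 1:
        raise ValueError("gene universe smaller than n_edges_per_node + 1")
    rng = np.random.default_rng(config.seed + _OFFSET_NETWORK)
    n = len(gene_universe)

    backbone = nx.barabasi_albert_graph(
        n, config.n_edges_per_node, seed=int(rng.integers(2**31))
    )
    edges: dict[tuple[str, str], np.ndarray] = {}

    def put(a: str, b: str, scores: np.ndarray) -> None:
        key = (a, b) if a <= b else (b, a)
        if key in edges:
            edges[key] = np.maximum(edges[key], scores)
        else:
            edges[key] = scores

    backbone_edges = list(backbone.edges())
    n_bg = len(backbone_edges)
    passing = rng.random(n_bg) < config.frac_pass
    hi = _passing_scores(rng, n_bg)
    lo = _failing_scores(rng, n_bg)
    for idx, (i, j) in enumerate(backbone_edges):
        put(gene_universe[i], gene_universe[j], hi[idx] if passing[idx] else lo[idx])

    hubs: list[str] = []
    de_genes = sorted(set(truth.de_genes) & set(gene_universe))
    if config.n_planted_hubs:
        n_bridges = max(0, config.n_planted_hubs - 1)
        needed = config.n_planted_hubs * (1 + config.n_hub_neighbors) + n_bridges
        if len(de_genes) < needed:
            raise ValueError(
                f"need {needed} distinct DE genes to plant {config.n_planted_hubs} hubs, "
                f"have {len(de_genes)}"
            )
        chosen = rng.choice(len(de_genes), size=needed, replace=False)
        pool = [de_genes[i] for i in chosen]
        hubs = pool[: config.n_planted_hubs]
        bridges = pool[config.n_planted_hubs : config.n_planted_hubs + n_bridges]
        leaves = pool[config.n_planted_hubs + n_bridges :]
        for h_idx, hub in enumerate(hubs):
            mine = leaves[h_idx * config.n_hub_neighbors : (h_idx + 1) * config.n_hub_neighbors]
            scores = _passing_scores(rng, len(mine))
            for leaf, s in zip(mine, scores):
                put(hub, leaf, s)
        for b_idx, bridge in enumerate(bridges):
            s = _passing_scores(rng, 2)
            put(hubs[b_idx], bridge, s[0])
            put(bridge, hubs[b_idx + 1], s[1])

    rows = []
    for (a, b), (s_exp, s_db) in sorted(edges.items()):
        combined = combine_channels({"experiments": float(s_exp), "database": float(s_db)})
        rows.append({"protein1": a, "protein2": b, "experiments": float(s_exp),
                     "database": float(s_db), "combined_score": combined})
    table = pd.DataFrame(rows, columns=["protein1", "protein2", "experiments", "database", "combined_score"])
    new_truth = SimTruth(
        de_genes=truth.de_genes,
        hub_genes=tuple(hubs),
        enriched_terms=truth.enriched_terms,
        seed=truth.seed,
    )
    return table, new_truth


def simulate_annotations(
    gene_universe: list[str], config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, SimTruth]:
    """Annotation corpus with planted enriched terms.

    Term sizes are uniform on ``term_size_range``; the first
    ``n_enriched_terms`` terms draw ``enriched_frac`` (>= 75% by default
    configuration) of their members from the planted DE genes, the rest
    uniformly; categories rotate round-robin through the six built-in
    process categories.
    """
    config.validate()
    lo, hi = config.term_size_range
    if hi > len(gene_universe):
        raise ValueError("term_size_range max exceeds the gene universe")
    rng = np.random.default_rng(config.seed + _OFFSET_ANNOTATIONS)
    universe = list(gene_universe)
    de_genes = sorted(set(truth.de_genes) & set(universe))
    other = sorted(set(universe) - set(de_genes))

    rows = []
    enriched: list[str] = []
    for t in range(config.n_terms):
        tid = f"T{t:04d}"
        name = f"synthetic process {t}"
        cat = CATEGORIES[t % len(CATEGORIES)]
        size = int(rng.integers(lo, hi + 1))
        if t < config.n_enriched_terms and de_genes:
            n_from_de = min(math.ceil(config.enriched_frac * size), len(de_genes))
            picked = [de_genes[i] for i in rng.choice(len(de_genes), n_from_de, replace=False)]
            rest_pool = other if other else universe
            n_rest = size - n_from_de
            picked += [rest_pool[i] for i in rng.choice(len(rest_pool), min(n_rest, len(rest_pool)), replace=False)]
            enriched.append(tid)
        else:
            picked = [universe[i] for i in rng.choice(len(universe), size, replace=False)]
        for g in sorted(set(picked)):
            rows.append({"gene": g, "term_id": tid, "term_name": name, "category": cat})
    table = pd.DataFrame(rows, columns=["gene", "term_id", "term_name", "category"])
    new_truth = SimTruth(
        de_genes=truth.de_genes,
        hub_genes=truth.hub_genes,
        enriched_terms=tuple(enriched),
        seed=truth.seed,
    )
    return table, new_truth


def simulate_all(config: SimConfig):
    """Counts + design, edge table, annotations, and the combined truth."""
    counts, design, truth = simulate_counts(config)
    genes = list(counts.index)
    edges, truth = simulate_interactome(genes, config, truth)
    annotations, truth = simulate_annotations(genes, config, truth)
    return counts, design, edges, annotations, truth
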