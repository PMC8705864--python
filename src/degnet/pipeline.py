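"""End-to-end orchestration: counts -> DEGs -> network -> hubs -> enrichment.

Runs the stages in order on files or on freshly simulated inputs, writes
every stage artifact (TSV/GraphML/JSON) under one output directory, and
returns a machine-readable run report whose counts mirror the shape of
the underlying study design: total/up/down DEGs, surviving network size,
per-component summaries, the key-node table, the first-neighbor
subnetwork size, and significant-term counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import de, enrich, hubs, io, network, simulate

__all__ = ["PipelineConfig", "run_pipeline", "emit_key_table", "load_config"]

log = logging.getLogger("degnet")


@dataclass
class PipelineConfig:
    """Structured configuration for one pipeline run.

    Exactly one input mode is active: either the four input paths are
    given, or a ``simulate`` block generates them.
    """

    counts_path: str | None = None
    design_path: str | None = None
    edges_path: str | None = None
    annotations_path: str | None = None
    edge_dialect: str = "milli"
    simulate: simulate.SimConfig | None = None
    de_q_cutoff: float = 0.05
    net_threshold: float = 0.900
    net_channels: tuple[str, ...] = network.DEFAULT_CHANNELS
    net_prior: float = network.STRING_PRIOR
    z_cutoff: float = 1.96
    enrich_q_cutoff: float = 0.05
    enrich_min_K: int = 3
    background: str = "annotated"  # or "all" (all genes in the count matrix)
    keep_categories: tuple[str, ...] | None = None
    out_dir: str = "degnet_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = (self.counts_path, self.design_path, self.edges_path, self.annotations_path)
        if self.simulate is None and any(p is None for p in paths):
            raise ValueError("either all four input paths or a simulate block must be given")
        if self.simulate is not None and any(p is not None for p in paths):
            raise ValueError("input paths and a simulate block are mutually exclusive")
        for name, val, lo, hi in (
            ("de_q_cutoff", self.de_q_cutoff, 0.0, 1.0),
            ("net_threshold", self.net_threshold, 0.0, 1.0),
            ("enrich_q_cutoff", self.enrich_q_cutoff, 0.0, 1.0),
            ("net_prior", self.net_prior, 0.0, 1.0),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")
        if self.background not in ("annotated", "all"):
            raise ValueError("background must be 'annotated' or 'all'")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "term_size_range" in sim:
            sim["term_size_range"] = tuple(sim["term_size_range"])
        cfg.simulate = simulate.SimConfig(**sim)
    for name in ("net_channels", "keep_categories"):
        val = getattr(cfg, name)
        if isinstance(val, list):
            setattr(cfg, name, tuple(val))
    return cfg


def emit_key_table(de_table: pd.DataFrame, centrality: pd.DataFrame) -> pd.DataFrame:
    """Key-node report table: per-cohort means, fold change, betweenness
    and degree, sorted by descending betweenness, rounded to 2 decimals
    half-away-from-zero (rounding applied only here, at emission)."""
    missing = [g for g in centrality.index if g not in de_table.index]
    if missing:
        raise ValueError(f"key node(s) missing from the DE table: {missing}")
    joined = centrality.join(de_table[["mean_a", "mean_b", "log2fc"]], how="left")
    # stable: ties in betweenness fall back to ascending gene id
    joined = joined.sort_index().sort_values("betweenness", ascending=False, kind="stable")
    out = pd.DataFrame(
        {
            "gene": joined.index,
            "mean_a": io.round_half_away(joined["mean_a"].to_numpy()),
            "mean_b": io.round_half_away(joined["mean_b"].to_numpy()),
            "log2fc": io.round_half_away(joined["log2fc"].to_numpy()),
            "betweenness": io.round_half_away(joined["betweenness"].to_numpy()),
            "degree": joined["degree"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    return out


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        counts, design, edge_table, annotations, truth = simulate.simulate_all(sim_cfg)
        io.write_counts(counts, out / "counts.tsv")
        io.write_design(design, out / "design.tsv")
        io.write_edges(edge_table, out / "edges.tsv", dialect=config.edge_dialect)
        io.write_annotations(annotations, out / "annotations.tsv")
        truth.to_json(out / "truth.json")
        edges = network.read_edges(out / "edges.tsv", dialect=config.edge_dialect)
        return counts, design, edges, annotations
    counts = io.read_counts(config.counts_path)
    design = io.read_design(config.design_path)
    edges = network.read_edges(config.edges_path, dialect=config.edge_dialect)
    annotations = io.read_annotations(config.annotations_path)
    return counts, design, edges, annotations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under ``config.out_dir`` and
    return the run report (also written as ``report.json``).

    A stage failure leaves a ``FAILED_<stage>`` marker file next to any
    partial outputs and re-raises.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "parameters": {
        "de_q_cutoff": config.de_q_cutoff,
        "net_threshold": config.net_threshold,
        "net_channels": list(config.net_channels),
        "net_prior": config.net_prior,
        "z_cutoff": config.z_cutoff,
        "enrich_q_cutoff": config.enrich_q_cutoff,
        "enrich_min_K": config.enrich_min_K,
        "background": config.background,
        "keep_categories": list(config.keep_categories) if config.keep_categories else None,
    }}
    timings: dict = {}
    stage = "inputs"
    try:
        t0 = time.perf_counter()
        counts, design, edges, annotations = _load_inputs(config, out)
        timings[stage] = time.perf_counter() - t0
        report["stages"]["inputs"] = {
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "n_edges": len(edges),
            "n_annotation_rows": int(len(annotations)),
        }

        stage = "de"
        t0 = time.perf_counter()
        log.info("DE: q < %s, no fold-change cutoff", config.de_q_cutoff)
        de_table = de.run_de(counts, design, q_cutoff=config.de_q_cutoff)
        de_table.to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
        deg_set = set(de_table.index[de_table["is_deg"]])
        n_up = int((de_table["is_deg"] & (de_table["direction"] == "up")).sum())
        n_down = int((de_table["is_deg"] & (de_table["direction"] == "down")).sum())
        timings[stage] = time.perf_counter() - t0
        report["stages"]["de"] = {"n_deg": len(deg_set), "n_up": n_up, "n_down": n_down}

        stage = "network"
        t0 = time.perf_counter()
        log.info("network: channels %s, prior %s, combined >= %s",
                 config.net_channels, config.net_prior, config.net_threshold)
        if deg_set:
            g = network.build_network(
                edges, deg_set, threshold=config.net_threshold,
                channels=config.net_channels, prior=config.net_prior,
            )
        else:
            g = nx.Graph()
        network.write_edge_list(g, out / "network.tsv")
        if g.number_of_nodes():
            network.write_graphml(g, out / "network.graphml")
        timings[stage] = time.perf_counter() - t0
        report["stages"]["network"] = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
        }

        stage = "hubs"
        t0 = time.perf_counter()
        log.info("hubs: z > %s in the largest-diameter component", config.z_cutoff)
        key_nodes: list = []
        neighbor_nodes: set = set()
        components_out: list = []
        if g.number_of_nodes():
            comps = hubs.connected_components(g)
            components_out = [
                {"component_id": c.component_id, "n_nodes": c.n_nodes, "diameter": c.diameter}
                for c in comps
            ]
            main = hubs.select_main_component(g)
            bc = hubs.betweenness(main)
            z = hubs.zscores(bc)
            centrality = pd.DataFrame(
                {
                    "betweenness": pd.Series(bc),
                    "degree": pd.Series(dict(main.degree())),
                    "z": pd.Series(z),
                }
            ).sort_values("betweenness", ascending=False, kind="stable")
            centrality.index.name = "gene"
            centrality.to_csv(out / "centrality.tsv", sep="\t", index_label="gene")
            key_nodes = hubs.zscore_select(bc, cutoff=config.z_cutoff)
            if key_nodes:
                selection = hubs.neighbor_subnetwork(main, key_nodes)
                neighbor_nodes = set(selection.neighbor_nodes)
                sub = selection.subnetwork
                for node in sub.nodes:
                    up = bool(de_table.loc[node, "direction"] == "up")
                    sub.nodes[node]["direction"] = "up" if up else "down"
                    sub.nodes[node]["color"] = "red" if up else "blue"
                    sub.nodes[node]["is_key"] = node in selection.key_nodes
                network.write_graphml(sub, out / "subnetwork.graphml")
                network.write_edge_list(sub, out / "subnetwork.tsv")
                key_table = emit_key_table(de_table, centrality.loc[key_nodes])
                key_table.to_csv(out / "key_table.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0
        report["stages"]["hubs"] = {
            "components": components_out,
            "n_key_nodes": len(key_nodes),
            "key_nodes": list(key_nodes),
            "n_neighbor_nodes": len(neighbor_nodes),
            "subnetwork_n_nodes": len(key_nodes) + len(neighbor_nodes),
        }

        stage = "enrichment"
        t0 = time.perf_counter()
        query = set(key_nodes) | neighbor_nodes
        universe = list(counts.index) if config.background == "all" else None
        amap = enrich.AnnotationMap.from_frame(annotations, universe=universe)
        table = enrich.enrich(
            query, amap, min_K=config.enrich_min_K, q_cutoff=config.enrich_q_cutoff
        )
        if config.keep_categories is not None and len(table):
            table = enrich.categorize(table, config.keep_categories)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if len(table):
            bubble = table[["term_id", "score", "ratio", "category"]].rename(
                columns={"term_id": "term"}
            )
        else:
            bubble = pd.DataFrame(columns=["term", "score", "ratio", "category"])
        bubble.to_csv(out / "bubble.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0
        report["stages"]["enrichment"] = {
            "n_terms_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        }
    except Exception:
        (out / f"FAILED_{stage}").touch()
        log.exception("pipeline failed at stage %s", stage)
        raise

    report["timings"] = timings
    stable = {k: v for k, v in report.items() if k != "timings"}
    with open(out / "report.json", "w") as fh:
        json.dump(stable, fh, indent=1, sort_keys=True)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1, sort_keys=True)
    return report
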