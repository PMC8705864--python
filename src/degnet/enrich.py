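"""Overrepresentation analysis of annotation terms in a gene list.

One-sided hypergeometric test per term (upper tail: is the query list
enriched for the term's genes relative to the background universe?),
Benjamini-Hochberg correction across tested terms, and the bubble-plot
quantities used to summarize results: score = -ln(q) and ratio = k/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust

__all__ = ["AnnotationMap", "hypergeom_test", "enrich", "categorize"]

DEFAULT_MIN_K = 3
DEFAULT_Q_CUTOFF = 0.05


@dataclass(frozen=True)
class AnnotationMap:
    """Forward (term -> genes) and inverse (gene -> terms) annotation
    index over an explicit background universe."""

    terms: dict = field(repr=False)  # term_id -> (term_name, category, frozenset of genes)
    universe: frozenset = field(repr=False)

    def __post_init__(self) -> None:
        for tid, (_, _, genes) in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(f"term {tid!r} annotates genes outside the universe: {sorted(stray)[:5]}")

    @property
    def gene_index(self) -> dict:
        inv: dict = {}
        for tid, (_, _, genes) in self.terms.items():
            for g in genes:
                inv.setdefault(g, set()).add(tid)
        return inv

    @property
    def categories(self) -> set:
        return {cat for (_, cat, _) in self.terms.values()}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, universe=None) -> "AnnotationMap":
        """Build from a long (gene, term_id, term_name, category) table.

        With ``universe=None`` the background is the set of annotated
        genes; passing an explicit collection (e.g. all genes in the
        count matrix) widens it.
        """
        terms: dict = {}
        for tid, grp in frame.groupby("term_id", sort=True):
            name = str(grp["term_name"].iloc[0])
            cat = str(grp["category"].iloc[0])
            terms[str(tid)] = (name, cat, frozenset(map(str, grp["gene"])))
        annotated = frozenset().union(*(g for (_, _, g) in terms.values())) if terms else frozenset()
        uni = annotated if universe is None else frozenset(map(str, universe)) | annotated
        return cls(terms=terms, universe=uni)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``K`` universe genes carry the term, ``n`` genes were queried out of
    ``N``, ``k`` query genes carry the term.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    annotations: AnnotationMap,
    min_K: int = DEFAULT_MIN_K,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> pd.DataFrame:
    """Term-by-term overrepresentation table for a query gene list.

    Query genes outside the universe are dropped with a warning.  Terms
    need K >= ``min_K`` annotated genes and k >= 1 query hits to be
    tested; BH runs across all tested terms.  Rows are sorted by
    ascending q then term id and carry score = -ln(q) and ratio = k/K.
    """
    query = set(map(str, query))
    stray = query - annotations.universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the background universe were dropped",
            stacklevel=2,
        )
        query -= stray
    N = len(annotations.universe)
    n = len(query)
    columns = [
        "term_id", "term_name", "category", "k", "K", "n", "N",
        "pvalue", "qvalue", "score", "ratio", "significant",
    ]
    if n == 0:
        return pd.DataFrame(columns=columns)
    rows = []
    for tid, (name, cat, genes) in sorted(annotations.terms.items()):
        K = len(genes)
        if K < min_K:
            continue
        k = len(genes & query)
        if k < 1:
            continue
        p = hypergeom_test(k, K, n, N)
        rows.append({"term_id": tid, "term_name": name, "category": cat,
                     "k": k, "K": K, "n": n, "N": N, "pvalue": p})
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    with np.errstate(divide="ignore"):
        table["score"] = -np.log(table["qvalue"])
    table["ratio"] = table["k"] / table["K"]
    table["significant"] = table["qvalue"] < q_cutoff
    table = table.sort_values(["qvalue", "term_id"], kind="stable").reset_index(drop=True)
    return table[columns]


def categorize(table: pd.DataFrame, keep_categories) -> pd.DataFrame:
    """Restrict an enrichment table to chosen categories, keeping order."""
    keep = list(keep_categories)
    known = set(table["category"].unique())
    unknown = [c for c in keep if c not in known]
    if unknown:
        raise ValueError(f"unknown categor{'y' if len(unknown)==1 else 'ies'} {unknown}; known: {sorted(known)}")
    return table[table["category"].isin(keep)].reset_index(drop=True)
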