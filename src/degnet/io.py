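"""Flat-file readers/writers for the pipeline's tabular formats.

All formats are plain TSV: counts (first column gene id, header row of
sample ids), design (sample, cohort), STRING-detailed edges (protein1,
protein2, per-channel scores, combined_score), annotations (gene,
term_id, term_name, category).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import Design

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "write_edges",
    "read_annotations",
    "write_annotations",
    "round_half_away",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path, cohort_a: str | None = None) -> Design:
    return Design.from_frame(pd.read_csv(path, sep="\t", dtype=str), cohort_a=cohort_a)


def write_design(design: Design, path) -> None:
    pd.DataFrame(
        [{"sample": s, "cohort": c} for s, c in design.assignments.items()]
    ).to_csv(path, sep="\t", index=False)


def write_edges(edges: pd.DataFrame, path, dialect: str = "milli") -> None:
    """Write a STRING-detailed edge table; milli dialect rounds channel
    scores to integer 0-1000 as the real STRING dumps do."""
    out = edges.copy()
    score_cols = [c for c in out.columns if c not in ("protein1", "protein2")]
    if dialect == "milli":
        for c in score_cols:
            out[c] = (out[c] * 1000).round().astype(int)
    elif dialect != "fraction":
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "term_id", "term_name", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01), the
    convention used for the reported tables."""
    arr = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if np.isscalar(x):
        return float(out)
    return out
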