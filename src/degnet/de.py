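"""Two-cohort negative-binomial differential expression.

Implements the normalization/test chain used for bulk RNA-seq count
matrices: median-of-ratios size factors, per-gene method-of-moments
dispersion, a Wald test from a negative-binomial log-link GLM fit by
iteratively reweighted least squares (IRLS) with per-sample offsets, and
Benjamini-Hochberg correction.  A gene is called differentially expressed
(DEG) when its BH q-value falls below the cutoff; no fold-change filter is
ever applied.

The NB parameterization throughout is ``variance = mu + d * mu**2`` with
dispersion ``d >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Design",
    "size_factors",
    "normalized_counts",
    "normalized_means",
    "log2_fold_change",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "run_de",
]

DEFAULT_Q_CUTOFF = 0.05
DISPERSION_FLOOR = 1e-8
ZERO_MEAN_EPS = 1e-8


@dataclass(frozen=True)
class Design:
    """Assignment of samples to exactly two cohorts.

    ``cohort_a`` is the reference, so reported fold changes are
    ``log2(mean_b / mean_a)``.
    """

    assignments: dict[str, str] = field(repr=False)
    cohort_a: str = "A"
    cohort_b: str = "B"

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels != {self.cohort_a, self.cohort_b}:
            raise ValueError(
                f"design must use exactly cohorts {self.cohort_a!r}/{self.cohort_b!r}, got {sorted(labels)}"
            )
        for label in (self.cohort_a, self.cohort_b):
            n = sum(1 for v in self.assignments.values() if v == label)
            if n < 2:
                raise ValueError(f"cohort {label!r} has {n} samples; need >= 2")

    def samples(self, cohort: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cohort]

    def indicator(self, sample_ids) -> np.ndarray:
        """0/1 vector (1 = cohort B) in the order of ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples not assigned to a cohort: {missing}")
        return np.asarray(
            [1.0 if self.assignments[s] == self.cohort_b else 0.0 for s in sample_ids]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cohort_a: str | None = None) -> "Design":
        """Build from a (sample, cohort) table; reference defaults to the
        lexicographically smaller cohort label unless given."""
        assignments = dict(zip(frame["sample"], frame["cohort"]))
        labels = sorted(set(assignments.values()))
        if len(labels) != 2:
            raise ValueError(f"design table must contain exactly two cohorts, got {labels}")
        if cohort_a is None:
            cohort_a = labels[0]
        cohort_b = next(l for l in labels if l != cohort_a)
        return cls(assignments=assignments, cohort_a=cohort_a, cohort_b=cohort_b)


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("count matrix contains negative values")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with positive geometric mean across all
    samples (i.e. no zero count); ``s_j`` is the median over reference
    genes of ``counts[g, j] / geomean_g``.
    """
    _validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene with all-positive counts: median-of-ratios has no reference "
            "set and the pseudo-reference fallback is disabled"
        )
    ref = arr[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geomean[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors.reindex(counts.columns)


def normalized_means(
    counts: pd.DataFrame, design: Design, factors: pd.Series
) -> pd.DataFrame:
    """Arithmetic mean of normalized counts per cohort.

    Returns a frame with columns ``mean_a`` and ``mean_b`` indexed by gene.
    """
    norm = normalized_counts(counts, factors)
    mean_a = norm[design.samples(design.cohort_a)].mean(axis=1)
    mean_b = norm[design.samples(design.cohort_b)].mean(axis=1)
    return pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b})


def log2_fold_change(mean_a, mean_b, eps: float = ZERO_MEAN_EPS):
    """log2(mean_b / mean_a), with a pseudo-mean ``eps`` substituted for
    zero means.  Scalar in, scalar out; array in, array out.  A pair with
    both means zero yields NaN (undefined, to be flagged by the caller)."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("cohort means must be nonnegative")
    both_zero = (a == 0) & (b == 0)
    with np.errstate(divide="ignore"):
        lfc = np.log2(np.where(b == 0, eps, b)) - np.log2(np.where(a == 0, eps, a))
    lfc = np.where(both_zero, np.nan, lfc)
    if np.isscalar(mean_a) and np.isscalar(mean_b):
        return float(lfc)
    return lfc


def estimate_dispersion(
    counts: pd.DataFrame,
    design: Design,
    factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene method-of-moments dispersion on normalized counts.

    Within-cohort sample variances are pooled with their degrees of
    freedom; ``d = max(0, (pooled_var - mean) / mean**2)``, floored so the
    NB likelihood stays well-defined.  No trend fitting or shrinkage.
    """
    norm = normalized_counts(counts, factors)
    groups = [norm[design.samples(design.cohort_a)], norm[design.samples(design.cohort_b)]]
    ss = sum(
        ((g.to_numpy() - g.to_numpy().mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for g in groups
    )
    df = sum(g.shape[1] - 1 for g in groups)
    pooled_var = ss / df
    mean = norm.to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (pooled_var - mean) / mean**2
    d = np.where(mean > 0, d, 0.0)
    return pd.Series(np.maximum(d, floor), index=counts.index, name="dispersion")


def _irls_nb_wald(
    y: np.ndarray,
    x: np.ndarray,
    offsets: np.ndarray,
    disp: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Vectorized IRLS for per-gene NB GLMs sharing one two-level design.

    Model: log mu_gj = offset_j + b0_g + b1_g * x_j, Var = mu + d mu^2.
    Returns (b1, se_b1, converged) arrays over genes.
    """
    n_genes = y.shape[0]
    mu = y + 0.5
    eta = np.log(mu) - offsets[None, :]
    b0 = eta.mean(axis=1)
    b1 = np.zeros(n_genes)
    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    d = disp[:, None]
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
        mu = np.exp(eta + offsets[None, :])
        w = mu / (1.0 + d * mu)
        z = eta + (y - mu) / mu
        s1 = w.sum(axis=1)
        sx = (w * x).sum(axis=1)
        sxx = (w * x * x).sum(axis=1)
        sz = (w * z).sum(axis=1)
        sxz = (w * x * z).sum(axis=1)
        det = s1 * sxx - sx**2
        det = np.where(det > 0, det, np.nan)
        new_b0 = (sxx * sz - sx * sxz) / det
        new_b1 = (s1 * sxz - sx * sz) / det
        new_b0 = np.where(np.isfinite(new_b0), new_b0, b0)
        new_b1 = np.where(np.isfinite(new_b1), np.clip(new_b1, -30, 30), b1)
        step = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        just_converged = active & (step < tol)
        converged |= just_converged
        active &= ~just_converged
        b0, b1 = new_b0, new_b1
        if not active.any():
            break
    # final-state standard error at the converged coefficients
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
    mu = np.exp(eta + offsets[None, :])
    w = mu / (1.0 + d * mu)
    s1 = w.sum(axis=1)
    sx = (w * x).sum(axis=1)
    sxx = (w * x * x).sum(axis=1)
    det = s1 * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, s1 / det, np.nan))
    return b1, se, converged


def wald_test(
    counts: pd.DataFrame,
    design: Design,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> pd.DataFrame:
    """Per-gene NB Wald test between cohorts; returns the DE table.

    Columns: gene index, mean_a, mean_b, log2fc, stat, pvalue, qvalue,
    is_deg, direction, flag.  Genes with both cohort means zero are
    excluded from testing (pvalue NaN, flag ``zero``); IRLS failures get
    pvalue 1 and flag ``nonconverged``.  ``is_deg`` is ``qvalue <
    q_cutoff`` with no fold-change condition.
    """
    _validate_counts(counts)
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design, factors)

    means = normalized_means(counts, design, factors)
    both_zero = (means["mean_a"] == 0) & (means["mean_b"] == 0)
    any_zero_mean = ((means["mean_a"] == 0) | (means["mean_b"] == 0)) & ~both_zero
    lfc = log2_fold_change(means["mean_a"].to_numpy(), means["mean_b"].to_numpy())

    y = counts.to_numpy(dtype=float)
    x = design.indicator(counts.columns)
    offsets = np.log(factors.reindex(counts.columns).to_numpy(dtype=float))
    disp = dispersions.reindex(counts.index).to_numpy(dtype=float)

    testable = ~both_zero.to_numpy()
    stat = np.full(len(counts), np.nan)
    p = np.full(len(counts), np.nan)
    flag = np.where(both_zero.to_numpy(), "zero", "").astype(object)
    if testable.any():
        b1, se, conv = _irls_nb_wald(y[testable], x, offsets, disp[testable])
        w = np.where(se > 0, b1 / se, 0.0)
        p_t = 2.0 * stats.norm.sf(np.abs(w))
        p_t = np.where(conv, p_t, 1.0)
        w = np.where(conv, w, np.nan)
        stat[testable] = w
        p[testable] = p_t
        flags_t = np.where(conv, "", "nonconverged")
        flag[testable] = flags_t
    flag = np.where(any_zero_mean.to_numpy() & (flag == ""), "zero_mean", flag)

    q = np.full(len(counts), np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    is_deg = np.where(np.isnan(q), False, q < q_cutoff)
    direction = np.where(lfc > 0, "up", "down")

    return pd.DataFrame(
        {
            "mean_a": means["mean_a"],
            "mean_b": means["mean_b"],
            "log2fc": lfc,
            "stat": stat,
            "pvalue": p,
            "qvalue": q,
            "is_deg": is_deg.astype(bool),
            "direction": direction,
            "flag": flag,
        },
        index=counts.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the
    input order.  Ties are handled stably via a stable argsort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(
    counts: pd.DataFrame, design: Design, q_cutoff: float = DEFAULT_Q_CUTOFF
) -> pd.DataFrame:
    """Full DE chain: size factors -> dispersion -> Wald -> BH -> calls."""
    factors = size_factors(counts)
    dispersions = estimate_dispersion(counts, design, factors)
    return wald_test(counts, design, factors, dispersions, q_cutoff=q_cutoff)
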