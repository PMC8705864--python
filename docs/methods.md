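# Methods

This note records the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the known limitations.

## 1. Differential expression

### Model

Counts `c_gj` for gene `g` in sample `j` are negative binomial with mean
`s_j · μ_g(cohort)` and variance `μ + d_g μ²` (NB2 parameterization;
`d_g ≥ 0` is the gene's dispersion). The mean model is a log-link GLM,

    log μ_gj = log s_j + β0_g + β1_g · x_j ,

with `x_j = 1` for cohort B. `β1_g` is the natural-log fold change; the
Wald test asks whether it is zero.

### Size factors

Median-of-ratios: reference genes are those with a positive count in every
sample; `s_j` is the median over reference genes of `c_gj / geomean_g`.
Factors are reported as computed (no rescaling to geometric mean 1), so
they are defined up to a common scale; everything downstream is invariant
to that scale (it is absorbed by the GLM intercept and cancels in the
cohort-mean ratio). If no gene is positive everywhere the stage raises —
a pseudo-reference fallback is deliberately not provided, since with
typical bulk matrices the condition indicates an input problem.

### Dispersion

Per-gene method of moments on normalized counts: within-cohort sums of
squares pooled with `n_A + n_B − 2` degrees of freedom, and

    d_g = max(0, (pooled_var − mean) / mean²),

floored at `1e-8` so the NB weight `μ/(1 + dμ)` stays defined. There is
**no** trend fitting, no empirical-Bayes shrinkage, no outlier handling.
This is a deliberate simplification: the downstream analysis consumes only
the DEG set and the reported cohort means/fold changes, and the simple
estimator keeps the module self-contained and exactly testable. The cost
is calibration at small n, quantified below.

### Wald test and multiplicity

IRLS (max 100 iterations, tolerance 1e-8 on coefficients, linear predictor
clipped to ±30) at the fixed `d_g`; `SE(β̂1)` from the Fisher information;
two-sided p from the standard normal; Benjamini–Hochberg step-up across all
tested genes. Genes with both cohort means zero are excluded (flag `zero`);
IRLS failures get p = 1 (flag `nonconverged`). A gene is a DEG iff
`q < 0.05`. No fold-change filter exists anywhere in the code path.
Reported `log2fc` is `log2(mean_B/mean_A)` of normalized cohort means, with
a pseudo-mean `ε = 1e-8` substituted for a zero mean (flag `zero_mean`).

### Calibration, honestly measured

With the *true* dispersion plugged in, the null fraction of `p < 0.05` at
2000 genes, 8 vs 8, `d = 0.05` is 0.046–0.051 — the IRLS/Wald machinery is
calibrated. With the per-gene MoM plug-in it rises to ≈ 0.059–0.071
(mean ≈ 0.066), and the far tail inflates more (≈ 2.4× nominal), giving an
empirical FDR of ≈ 0.12 at `q < 0.05` on the default planted world instead
of the nominal ≤ 0.05. The mechanism is classical: dispersion estimates
that are too small by chance inflate their gene's Wald statistic, and BH
assumes valid p-values. Shrinking dispersions toward a mean–dispersion
trend is the standard remedy and is intentionally out of scope here; users
who need tight FDR control at small n should treat the q-values as
approximate. Sensitivity is unaffected in practice (≥ 0.99 at the default
effect size).

## 2. Interaction network

Channel scores are combined with the published naive-Bayes scheme used by
the STRING database: remove the prior from each channel,
`s' = max(0, (s − p)/(1 − p))` with `p = 0.041` by default; combine as a
noisy OR; re-add the prior once. Setting `prior=0` gives the plain noisy
OR ("simple" mode, used in several tests). Only the `experiments` and
`database` channels enter by default; both the channel set and the prior
are arguments. The filter keeps edges with combined score `≥` the
threshold — 0.900 passes exactly — between two DEGs; the node set is then
the surviving endpoints, which implements the degree-0 removal rule. Edge
tables are read in either the `milli` (integer 0–1000, STRING dumps) or
`fraction` dialect; duplicate undirected pairs merge by per-channel
maximum.

## 3. Hub selection

Components are found by BFS (networkx); each component's diameter is the
max over node pairs of unweighted shortest-path length. The "main"
component is the one with the largest diameter — ties broken by node
count, then by smallest node id, so selection is deterministic. The
diameter criterion (rather than node count) favors elongated, pathway-like
components over dense cliques.

Betweenness centrality is computed by an in-package implementation of
Brandes' accumulation (cross-checked in the tests against both a
brute-force all-shortest-paths enumeration and networkx), normalized by
`(n−1)(n−2)/2` so values lie in [0, 1]. Z-scores use the **population**
standard deviation of the selected component's values: the component is
the entire population being normalized, not a sample from a larger one.
Normalization is per-component, not network-wide; a flag could pool all
nodes instead, but a component-local distribution is the one the selected
nodes are actually outliers of. Selection is strict: `z > 1.96`, the
upper 2.5% tail of a normal — a degenerate (zero-spread) distribution
selects nothing, with a warning. The first-neighbor subnetwork is induced
on keys ∪ neighbors, so neighbor–neighbor edges are retained; exported
GraphML carries `direction` (up/down by fold-change sign), a red/blue
`color` attribute, and `is_key`.

## 4. Enrichment

One-sided (overrepresentation-only) hypergeometric upper tail
`P(X ≥ k)` per term, via `scipy.stats.hypergeom.sf` (verified against
exact rational enumeration for every instance with `N ≤ 25`). Terms need
`K ≥ 3` annotated genes and `k ≥ 1` hits; BH runs across tested terms;
`score = −ln(q)` (natural log) and `ratio = k/K` feed a bubble-plot
export. The background universe defaults to the annotated genes
(`background="annotated"`); `background="all"` widens it to every gene in
the count matrix. Neither choice is canonical — genome-wide backgrounds
make sparse annotation corpora look more enriched — so the default is the
more conservative one and both are exposed. Query genes outside the
universe are dropped with a warning, not an error. Categories are a data
column of the annotation table; the "keep these categories" step of a
curated figure is modeled as an explicit filter, not keyword matching.

## 5. Synthetic world

Defaults (all in `SimConfig`, one global seed expanded to per-stage child
seeds by fixed offsets):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | transcriptome size |
| `n_samples_a/b` | 8 / 8 | cohort sizes |
| `frac_de` | 0.10 | fraction of genes with a planted effect |
| `lfc_magnitude` | 2.0 | planted |log2 FC|, random sign |
| `mean_log_mu`, `sd_log_mu` | ln 100, 1.0 | LogNormal baseline means |
| `dispersion` | 0.05 | NB overdispersion, `var = μ + dμ²` |
| `n_edges_per_node` | 2 | preferential-attachment density |
| `n_planted_hubs` | 3 | DE genes wired as high-betweenness hubs |
| `n_hub_neighbors` | 15 | DE star neighbors per hub |
| `frac_pass` | 0.5 | backbone edges given filter-passing scores |
| `n_terms` | 50 | annotation terms, sizes uniform in (20, 40) |
| `n_enriched_terms` | 5 | terms drawing 80% of members from DE genes |

Evidence scores are Beta(40, 2) for passing edges (mode ≈ 0.97; two such
channels recombine well above 0.9) and Beta(2, 8) for failing ones, so the
0.900 filter genuinely separates the two populations. Hub planting wires
each hub to DE genes specifically — the downstream network keeps only DEGs
— and chains consecutive hubs through dedicated DE bridge genes, so the
planted blob is, with high probability, the largest-diameter component and
each hub lands in the `z > 1.96` tail. The bridge genes themselves acquire
high betweenness and are legitimately selected alongside the hubs.

What the generator does **not** emulate: per-sample library-size
variation (size factors are exercised by dedicated tests instead), batch
effects or covariates, gene–gene expression correlation, a real scale-free
degree distribution *within* the DEG subgraph, GO DAG structure/term
ancestry, and annotation bias toward well-studied genes. A green
recovery test therefore establishes that the chain recovers planted
structure under the model's own assumptions — not performance on real
cohorts, where dispersion trends, correlation and annotation incompleteness
all bite.

## 6. Numerical conventions

- Rounding for report tables: 2 decimals, half away from zero, applied at
  emission only; internal computation is never rounded.
- BH is the exact step-up `q_(i) = min_{j≥i} p_(j)·m/j`, stable under ties.
- Betweenness ties in key-node ordering break by gene id.
- All randomness flows from `numpy.random.default_rng(seed + stage_offset)`;
  identical config + seed gives byte-identical artifacts (timings are
  written to a separate file so `report.json` is reproducible).

## 7. Known limitations

- FDR at small n runs above nominal (see §1); this is a property of
  unshrunk per-gene dispersions, documented rather than patched.
- The diameter-based main-component rule is sensible for sparse induced
  networks but can be unstable when several components tie at small
  diameters; the tie-break makes it deterministic, not more meaningful.
- Betweenness is recomputed exactly (O(V·E) per component); components
  beyond ~10⁴ nodes would need sampling-based approximations that are out
  of scope.
- The enrichment stage queries the key genes' first-neighbor subnetwork
  (matching the analysis pattern the pipeline mirrors); recovery of
  planted terms is assessed against the DEG set, which is the structure
  the generator actually plants.
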