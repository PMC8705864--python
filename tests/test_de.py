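"""Unit tests for normalization, dispersion, the NB Wald test and BH."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from degnet import de, simulate

from _oracles import brute_force_bh


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        counts = pd.DataFrame([[5, 5], [7, 7]], index=["g1", "g2"], columns=["s1", "s2"])
        f = de.size_factors(counts)
        assert np.allclose(f, [1.0, 1.0])

    def test_hand_computed_two_by_two(self):
        # geometric mean of each gene is 4; ratios are 0.5 and 2
        counts = pd.DataFrame([[2, 8], [2, 8]], index=["g1", "g2"], columns=["s1", "s2"])
        f = de.size_factors(counts)
        assert np.allclose(f, [0.5, 2.0])

    def test_scale_equivariance_per_sample(self, toy_counts):
        """Tripling one sample's library triples its size factor relative
        to every other sample (the factors are defined up to a common
        scale: the per-gene geometric means shift too, so only factor
        ratios are equivariant)."""
        f = de.size_factors(toy_counts)
        scaled = toy_counts.copy()
        scaled["b2"] = scaled["b2"] * 3
        f_scaled = de.size_factors(scaled)
        others = [c for c in toy_counts.columns if c != "b2"]
        ratios = (f_scaled["b2"] / f_scaled[others]).to_numpy()
        ratios_before = (f["b2"] / f[others]).to_numpy()
        assert np.allclose(ratios, 3 * ratios_before)
        # normalized counts of the scaled sample are restored up to the
        # common rescaling, so cohort means keep their ratios
        norm = de.normalized_counts(scaled, f_scaled)
        norm0 = de.normalized_counts(toy_counts, f)
        assert np.allclose(norm / norm.iloc[:, 0].to_numpy()[:, None],
                           norm0 / norm0.iloc[:, 0].to_numpy()[:, None])

    def test_gene_permutation_invariance(self, toy_counts):
        f = de.size_factors(toy_counts)
        rng = np.random.default_rng(3)
        perm = toy_counts.iloc[rng.permutation(len(toy_counts))]
        assert np.allclose(de.size_factors(perm), f)

    def test_no_reference_gene_is_an_error(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], index=["g1", "g2"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.size_factors(counts)


class TestNormalizedMeans:
    def test_unit_factors_give_raw_means(self, toy_counts, toy_design):
        f = pd.Series(1.0, index=toy_counts.columns)
        means = de.normalized_means(toy_counts, toy_design, f)
        raw_a = toy_counts[["a1", "a2", "a3"]].mean(axis=1)
        assert np.allclose(means["mean_a"], raw_a)

    def test_identical_cohorts_give_zero_lfc(self, toy_design):
        block = np.tile([[10.0], [40.0]], (1, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]).astype(int),
            index=["g1", "g2"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        f = de.size_factors(counts)
        means = de.normalized_means(counts, toy_design, f)
        lfc = de.log2_fold_change(means["mean_a"].to_numpy(), means["mean_b"].to_numpy())
        assert np.allclose(lfc, 0.0)


class TestLog2FoldChange:
    def test_symmetric_means_give_zero(self):
        assert de.log2_fold_change(123.4, 123.4) == 0.0

    def test_zero_baseline_uses_pseudo_mean(self):
        lfc = de.log2_fold_change(0.0, 20.49, eps=1e-8)
        assert lfc == pytest.approx(np.log2(20.49 / 1e-8))

    def test_both_zero_is_undefined(self):
        assert np.isnan(de.log2_fold_change(0.0, 0.0))

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            de.log2_fold_change(-1.0, 5.0)


class TestEstimateDispersion:
    def test_poisson_like_gene_floored(self, toy_design):
        # constant-ish Poisson rows at large n: variance ~ mean -> d ~ 0
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(200.0, size=(30, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        f = pd.Series(1.0, index=counts.columns)
        d = de.estimate_dispersion(counts, toy_design, f)
        # noisy at n=6, but centred near zero: median well below the true
        # NB alternative of e.g. 0.1
        assert d.median() < 0.02

    def test_constant_gene_hits_floor(self, toy_design):
        counts = pd.DataFrame(
            np.full((3, 6), 17),
            index=["g1", "g2", "g3"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        f = pd.Series(1.0, index=counts.columns)
        d = de.estimate_dispersion(counts, toy_design, f)
        assert (d == de.DISPERSION_FLOOR).all()

    def test_monte_carlo_calibration(self):
        # true d=0.2 at mu=100, n=50 per cohort: within 50% relative
        # error in >= 90% of 200 seeded replicates
        rng = np.random.default_rng(2024)
        mu, d_true, n = 100.0, 0.2, 50
        size = 1.0 / d_true
        p = size / (size + mu)
        ok = 0
        design = de.Design(
            assignments={**{f"a{i}": "A" for i in range(n)}, **{f"b{i}": "B" for i in range(n)}}
        )
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        for _ in range(200):
            counts = pd.DataFrame(
                rng.negative_binomial(size, p, size=(1, 2 * n)), index=["g"], columns=cols
            )
            f = pd.Series(1.0, index=cols)
            d_hat = de.estimate_dispersion(counts, design, f).iloc[0]
            ok += abs(d_hat - d_true) / d_true <= 0.5
        assert ok / 200 >= 0.90


class TestWaldTest:
    def test_identical_cohorts_give_null_statistic(self, toy_design):
        block = np.tile([[25.0], [80.0], [400.0]], (1, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]).astype(int),
            index=["g1", "g2", "g3"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        tab = de.run_de(counts, toy_design)
        assert np.allclose(tab["stat"], 0.0, atol=1e-6)
        assert np.allclose(tab["pvalue"], 1.0, atol=1e-6)

    def test_matches_statsmodels_glm(self, toy_counts, toy_design):
        """Independent cross-check: statsmodels NB GLM with the same fixed
        dispersion, offsets and design reproduces coefficient and SE."""
        sm = pytest.importorskip("statsmodels.api")
        factors = de.size_factors(toy_counts)
        disp = pd.Series(0.08, index=toy_counts.index)
        tab = de.wald_test(toy_counts, toy_design, factors, disp)
        x = np.column_stack([np.ones(6), toy_design.indicator(toy_counts.columns)])
        offset = np.log(factors.to_numpy())
        for gene in toy_counts.index[:8]:
            y = toy_counts.loc[gene].to_numpy()
            model = sm.GLM(
                y, x, family=sm.families.NegativeBinomial(alpha=0.08), offset=offset
            ).fit()
            wald_sm = model.params[1] / model.bse[1]
            assert tab.loc[gene, "stat"] == pytest.approx(wald_sm, rel=1e-4)

    def test_deg_calls_invariant_to_depth_rescaling(self, small_world):
        counts, design, *_ = small_world
        tab = de.run_de(counts, design)
        rng = np.random.default_rng(9)
        depths = rng.uniform(0.5, 2.0, size=counts.shape[1])
        # integer-valued rescaling keeps the count model exact
        scaled = (counts * depths).round().astype(int)
        tab_scaled = de.run_de(scaled, design)
        agree = (tab["is_deg"] == tab_scaled["is_deg"]).mean()
        # rounding perturbs individual counts, so demand near-identity
        assert agree > 0.97

    def test_both_cohorts_zero_excluded(self, toy_design):
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 0, 0], [30, 31, 29, 60, 62, 58]],
            index=["gz", "g1"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        tab = de.run_de(counts, toy_design)
        assert tab.loc["gz", "flag"] == "zero"
        assert np.isnan(tab.loc["gz", "pvalue"])
        assert not tab.loc["gz", "is_deg"]

    def test_no_fold_change_cutoff_is_applied(self):
        """A q < 0.05 gene with |log2fc| ~ 0.01 is still called a DEG."""
        n = 40
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        design = de.Design(
            assignments={**{f"a{i}": "A" for i in range(n)}, **{f"b{i}": "B" for i in range(n)}}
        )
        # constant, huge counts: tiny fold change, enormous power; the
        # anchor genes pin the median-of-ratios factors at exactly 1
        row = [100000] * n + [100696] * n
        anchors = [[v] * (2 * n) for v in (50, 120, 300, 800, 2000, 5000)]
        counts = pd.DataFrame(
            [row] + anchors,
            index=["g_small_fc"] + [f"anchor{i}" for i in range(6)],
            columns=cols,
        )
        tab = de.run_de(counts, design)
        lfc = tab.loc["g_small_fc", "log2fc"]
        assert abs(lfc) == pytest.approx(0.01, abs=2e-3)
        assert tab.loc["g_small_fc", "qvalue"] < 0.05
        assert bool(tab.loc["g_small_fc", "is_deg"])


class TestBHAdjust:
    def test_step_up_worked_example(self):
        q = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert de.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_ones(self):
        assert np.allclose(de.bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(de.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(23)
        p = rng.uniform(size=200)
        assert np.allclose(de.bh_adjust(p), mt.multipletests(p, method="fdr_bh")[1])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    def test_monotone_along_sorted_order(self, p):
        q = de.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDesign:
    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            de.Design(assignments={"s1": "A", "s2": "A", "s3": "A", "s4": "A"})

    def test_requires_two_samples_per_cohort(self):
        with pytest.raises(ValueError, match="need >= 2"):
            de.Design(assignments={"s1": "A", "s2": "B", "s3": "B"})

    def test_null_p_values_nearly_uniform(self):
        """KS distance of null Wald p-values from U(0,1) below 0.05."""
        cfg = dataclasses.replace(simulate.SimConfig(), frac_de=0.0, seed=1)
        counts, design, _ = simulate.simulate_counts(cfg)
        tab = de.run_de(counts, design)
        p = np.sort(tab["pvalue"].to_numpy())
        grid = np.arange(1, len(p) + 1) / len(p)
        ks = np.max(np.abs(p - grid))
        assert ks < 0.05
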