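import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stressmodes.data import CountMatrix, Design
from stressmodes.de import (
    adjust_bh,
    estimate_dispersion,
    estimate_size_factors,
    test_contrast as wald_contrast,
)
from stressmodes.errors import NormalizationError, ValidationError
from stressmodes.simulate import SimConfig, default_design, simulate_dataset


def matrix(values, samples=None):
    values = np.atleast_2d(values)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)
    )


def two_group_design(n_per_group, treatment="CT"):
    mapping = {f"ck{r}": "CK" for r in range(n_per_group)}
    mapping.update({f"t{r}": treatment for r in range(n_per_group)})
    return Design(mapping)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = matrix(np.tile([[10], [40], [7]], (1, 4)))
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_sample_closed_form(self):
        """B = 2A for every gene: factors are (1/sqrt(2), sqrt(2))."""
        a = np.array([10, 20, 50, 8])
        counts = matrix(np.column_stack([a, 2 * a]))
        np.testing.assert_allclose(
            estimate_size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_single_gene_hand_calculation(self):
        counts = matrix([[10, 40]])
        np.testing.assert_allclose(estimate_size_factors(counts), [0.5, 2.0])

    def test_no_universally_expressed_gene_raises(self):
        counts = matrix([[0, 5], [5, 0]])
        with pytest.raises(NormalizationError):
            estimate_size_factors(counts)

    def test_matches_pydeseq2_median_of_ratios(self):
        """Independent oracle: the reference DESeq2 implementation."""
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(3)
        depth = np.array([0.6, 1.0, 1.4, 2.0])
        mu = rng.lognormal(4, 1, size=(80, 1))
        counts_df = pd.DataFrame(
            rng.poisson(mu * depth[None, :]),
            index=[f"g{i}" for i in range(80)],
            columns=list("abcd"),
        )
        meta = pd.DataFrame({"condition": ["CK", "CK", "CT", "CT"]}, index=list("abcd"))
        dds = pydeseq2_dds.DeseqDataSet(
            counts=counts_df.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        ours = estimate_size_factors(CountMatrix(counts_df)).to_numpy()
        np.testing.assert_allclose(ours, dds.obs["size_factors"].to_numpy(), rtol=1e-8)


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        cfg = SimConfig(
            n_genes=60, replicates=50, mode_fractions={}, dispersion=0.0,
            baseline_log_mean=np.log(200.0), baseline_log_sd=0.0, rng_seed=4,
        )
        _, design, counts = simulate_dataset(cfg)
        sf = estimate_size_factors(counts)
        phi = estimate_dispersion(counts, sf, design)
        assert phi.median() < 0.02

    def test_constant_counts_hit_the_floor(self):
        counts = matrix(np.full((3, 4), 9), samples=["a", "b", "c", "d"])
        design = Design({"a": "CK", "b": "CK", "c": "CT", "d": "CT"})
        sf = estimate_size_factors(counts)
        phi = estimate_dispersion(counts, sf, design, floor=1e-8)
        np.testing.assert_allclose(phi, 1e-8)

    def test_nb_dispersion_recovered_within_band(self):
        cfg = SimConfig(
            n_genes=60, replicates=50, mode_fractions={}, dispersion=0.1,
            baseline_log_mean=np.log(200.0), baseline_log_sd=0.0, rng_seed=8,
        )
        _, design, counts = simulate_dataset(cfg)
        sf = estimate_size_factors(counts)
        phi = estimate_dispersion(counts, sf, design)
        assert 0.05 < phi.median() < 0.2

    def test_singleton_condition_rejected(self):
        counts = matrix(np.full((2, 3), 5), samples=["a", "b", "c"])
        design = Design.__new__(Design)
        design.mapping = {"a": "CK", "b": "CK", "c": "CT"}
        sf = pd.Series(1.0, index=["a", "b", "c"])
        with pytest.raises(ValidationError, match="CT"):
            estimate_dispersion(counts, sf, design)


class TestAdjustBH:
    def bh_oracle(self, p):
        """Hand-coded step-up rule: q_(i) = min_{j>=i} p_(j) m / j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        return q

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identity_cases(self):
        np.testing.assert_allclose(adjust_bh([0.05]), [0.05])
        np.testing.assert_allclose(adjust_bh([1.0, 1.0]), [1.0, 1.0])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_matches_hand_oracle(self, pvals):
        np.testing.assert_allclose(adjust_bh(pvals), self.bh_oracle(pvals), atol=1e-12)

    def test_monotone_in_sorted_order_and_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = adjust_bh(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.2])


class TestContrast:
    def test_null_pvalues_uniform(self):
        """No planted effects, many replicates: p-values pass a KS
        uniformity check at the 1% level."""
        cfg = SimConfig(n_genes=400, replicates=60, mode_fractions={}, dispersion=0.1, rng_seed=0)
        _, design, counts = simulate_dataset(cfg)
        res = wald_contrast(counts, design, "CT")
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01
        assert np.abs(res["log2fc"]).median() < 0.2

    def test_planted_effect_recovered(self):
        """|L| = 2 at mu = 100, phi = 0.1, 3 replicates: at least 95% of
        genes are significant with estimated L within [1, 3] in magnitude."""
        cfg = SimConfig(
            n_genes=1000, replicates=3, mode_fractions={"similar": 1.0},
            effect_size=2.0, baseline_log_mean=np.log(100.0), baseline_log_sd=0.0,
            dispersion=0.1, rng_seed=21,
        )
        truth, design, counts = simulate_dataset(cfg)
        res = wald_contrast(counts, design, "CT")
        est = res["log2fc"] * truth["s_ct"]  # orient by planted sign
        ok = res["significant"] & (est > 1) & (est < 3)
        assert ok.mean() >= 0.95

    def test_all_zero_gene_degenerates(self):
        values = np.array([[0, 0, 0, 0], [10, 12, 30, 28]])
        counts = matrix(values, samples=["a", "b", "c", "d"])
        design = Design({"a": "CK", "b": "CK", "c": "CT", "d": "CT"})
        res = wald_contrast(counts, design, "CT")
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "pvalue"] == 1.0

    def test_control_vs_itself_rejected(self):
        cfg = SimConfig(n_genes=10, rng_seed=0)
        _, design, counts = simulate_dataset(cfg)
        with pytest.raises(ValidationError):
            wald_contrast(counts, design, "CK")

    def test_result_invariants(self, planted_run):
        _, _, _, _, results = planted_run
        for table in results.contrasts.values():
            assert (table["qvalue"] >= table["pvalue"] - 1e-12).all()
            assert table["qvalue"].between(0, 1).all()
            sig = table[table["significant"]]
            assert (sig["direction"] != "none").all()
            assert (np.sign(sig["log2fc"]) == np.where(sig["direction"] == "up", 1, -1)).all()
            assert (table.loc[~table["significant"], "direction"] == "none").all()

    def test_scale_invariance_of_calls(self):
        """Multiplying one sample's counts by a constant changes size
        factors but leaves significance calls essentially unchanged."""
        cfg = SimConfig(n_genes=800, rng_seed=17)
        truth, design, counts = simulate_dataset(cfg)
        res1 = wald_contrast(counts, design, "CT")
        scaled = counts.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        counts2 = CountMatrix(scaled)
        res2 = wald_contrast(counts2, design, "CT")
        sf2 = estimate_size_factors(counts2)
        assert sf2.iloc[0] > 2  # normalization absorbed the scaling
        agreement = (res1["significant"] == res2["significant"]).mean()
        assert agreement >= 0.99

    def test_direction_concordance_with_pydeseq2(self):
        """The reference DESeq2 implementation agrees on direction for
        genes both engines call significant."""
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        from pydeseq2.ds import DeseqStats

        cfg = SimConfig(n_genes=300, rng_seed=23)
        truth, design, counts = simulate_dataset(cfg)
        res = wald_contrast(counts, design, "CT")

        samples = design.samples("CK") + design.samples("CT")
        meta = pd.DataFrame({"condition": [design.mapping[s] for s in samples]}, index=samples)
        dds = pydeseq2_dds.DeseqDataSet(
            counts=counts.counts[samples].T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "CT", "CK"], quiet=True)
        ds.summary()
        ref = ds.results_df
        both = res.index[(res["qvalue"] < 0.01) & (ref["padj"] < 0.01)]
        assert len(both) > 50
        agree = (np.sign(res.loc[both, "log2fc"]) == np.sign(ref.loc[both, "log2FoldChange"])).mean()
        assert agree > 0.99


def test_fdr_controlled_on_null_simulations():
    """Complete-null simulations: the fraction of q < 0.05 calls stays
    within binomial tolerance of the nominal level (a smaller, faster
    version of the dedicated acceptance check)."""
    n_genes, seeds = 500, 5
    calls = total = 0
    for seed in range(seeds):
        cfg = SimConfig(n_genes=n_genes, mode_fractions={}, rng_seed=100 + seed)
        _, design, counts = simulate_dataset(cfg)
        res = wald_contrast(counts, design, "CT")
        calls += int(res["significant"].sum())
        total += n_genes
    assert calls / total <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)
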