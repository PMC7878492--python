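"""Differential-modification tests: normalization recovery, NB GLM vs
independent fitters, permutation calibration at reduced scale, threshold
logic, enrichment, and the concentration curve."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hmcseal import diffmod, synthetic
from hmcseal._stats import bh_adjust
from hmcseal.diffmod import (
    call_differential,
    cytoband_enrichment,
    empirical_pvalues,
    filter_nonzero_variance,
    nb_wald_test,
    signal_concentration,
    size_factors,
)


class TestSizeFactors:
    def test_scaling_property(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(100, 1)).astype(float) + 1
        counts = pd.DataFrame({"s1": base[:, 0], "s2": 2 * base[:, 0]})
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 3], "b": [5, 9, 3], "c": [5, 9, 3]})
        sf = size_factors(counts)
        assert sf.nunique() == 1

    def test_recovers_truth_within_five_percent(self):
        cohort = synthetic.generate_cohort(10, 10, seed=31)
        ann = synthetic.generate_annotation(1000, 2, 60_000_000, seed=32)
        counts, truth = synthetic.generate_counts(
            cohort, ann, 0, 0.0, 0.1, 0.4, seed=33)
        sf = size_factors(filter_nonzero_variance(counts))
        true = np.array([truth.sample_size_factors[s] for s in sf.index])
        ratio = sf.to_numpy() / true
        assert np.abs(ratio / ratio.mean() - 1).max() < 0.05

    def test_matches_deseq2_reference(self):
        # median-of-ratios cross-checked against the pydeseq2 implementation
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(40, size=(200, 8)) + 1,
                              columns=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({"condition": ["A", "B"] * 4},
                            index=counts.columns)
        dds = pydeseq2_dds.DeseqDataSet(counts=counts.T, metadata=meta,
                                        design="~condition", quiet=True)
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"], dtype=float)
        np.testing.assert_allclose(size_factors(counts).to_numpy(), ref,
                                   rtol=1e-6)

    def test_all_zero_gene_handling(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(counts)
        sf = size_factors(counts, on_all_zero="pseudo")
        assert (sf > 0).all()

    def test_normalized_counts_scale_invariant(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(30, size=(50, 4)) + 1,
                              columns=list("abcd"))
        scales = pd.Series([1.0, 2.5, 0.5, 3.0], index=list("abcd"))
        scaled = counts * scales
        # rescaling samples rescales the factors, so normalized counts are
        # unchanged up to one global constant (the scales' geometric mean)
        n1 = diffmod.normalized_counts(counts, size_factors(counts))
        n2 = diffmod.normalized_counts(scaled, size_factors(scaled))
        ratio = (n2 / n1).to_numpy().ravel()
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)


class TestFilter:
    def test_constant_and_allzero_removed(self):
        counts = pd.DataFrame({"a": [5, 0, 0, 1], "b": [5, 0, 1, 2],
                               "c": [5, 0, 0, 3]},
                              index=["const", "zero", "varies", "varies2"])
        out = filter_nonzero_variance(counts)
        assert list(out.index) == ["varies", "varies2"]

    def test_empty_result_raises(self):
        counts = pd.DataFrame({"a": [5], "b": [5]})
        with pytest.raises(ValueError):
            filter_nonzero_variance(counts)


class TestNBWald:
    def test_null_data_centered(self):
        cohort = synthetic.generate_cohort(40, 40, seed=41)
        ann = synthetic.generate_annotation(150, 2, 10_000_000, seed=42)
        counts, _ = synthetic.generate_counts(cohort, ann, 0, 0.0, 0.05, 0.2,
                                              seed=43)
        tab = nb_wald_test(filter_nonzero_variance(counts), cohort)
        assert abs(tab["log2fc"].mean()) < 0.05
        assert tab["wald_z"].abs().median() < 1.5

    def test_poisson_limit_matches_glm_oracle(self):
        # dispersion ~ 0: estimates agree with an independent Poisson GLM
        import statsmodels.api as sm

        cohort = synthetic.generate_cohort(30, 30, seed=44)
        ann = synthetic.generate_annotation(20, 1, 2_000_000, seed=45)
        counts, _ = synthetic.generate_counts(
            cohort, ann, 3, 1.0, dispersion=0.0, libsize_cv=0.0, seed=46)
        counts = filter_nonzero_variance(counts)
        sf = pd.Series(1.0, index=counts.columns)
        tab = nb_wald_test(counts, cohort, sf=sf)
        X, names = diffmod.design_matrix(cohort)
        j = names.index("subtype_FL")
        for g in counts.index[:8]:
            fit = sm.GLM(counts.loc[g].to_numpy(), X,
                         family=sm.families.Poisson()).fit()
            assert tab.loc[g, "log2fc"] == pytest.approx(
                fit.params[j] / np.log(2), abs=0.02)
            assert tab.loc[g, "se"] == pytest.approx(
                fit.bse[j] / np.log(2), rel=0.1)

    def test_planted_effect_recovered(self):
        # 20 planted genes keep the Monte-Carlo error of the mean (~0.03)
        # well inside the 0.1 recovery tolerance
        cohort = synthetic.generate_cohort(48, 25, seed=47)
        ann = synthetic.generate_annotation(600, 2, 40_000_000, seed=48)
        counts, truth = synthetic.generate_counts(
            cohort, ann, 20, 1.0, 0.1, 0.3, seed=49)
        tab = nb_wald_test(filter_nonzero_variance(counts), cohort)
        est = tab.loc[truth.planted_genes, "log2fc"].abs().mean()
        assert abs(est - 1.0) < 0.1

    def test_direction_consistent_with_sign(self, small_counts, small_cohort):
        counts, _ = small_counts
        tab = nb_wald_test(filter_nonzero_variance(counts), small_cohort)
        up = tab["direction"] == "up_in_FL"
        assert ((tab["log2fc"] >= 0) == up).all()


@pytest.fixture(scope="module")
def null_fit():
    cohort = synthetic.generate_cohort(18, 18, seed=51)
    ann = synthetic.generate_annotation(300, 2, 20_000_000, seed=52)
    counts, _ = synthetic.generate_counts(cohort, ann, 0, 0.0, 0.1, 0.3,
                                          seed=53)
    counts = filter_nonzero_variance(counts)
    sf = size_factors(counts)
    tab = nb_wald_test(counts, cohort, sf=sf)
    return counts, cohort, sf, tab


class TestEmpiricalP:
    def test_null_calibration_reduced_scale(self, null_fit):
        counts, cohort, sf, tab = null_fit
        emp = empirical_pvalues(counts, cohort, sf=sf, B=200, seed=54,
                                table=tab)
        e = emp.dropna().to_numpy()
        assert stats.kstest(e, "uniform").pvalue > 0.01

    def test_extreme_statistic_gets_minimal_p(self, null_fit):
        counts, cohort, sf, tab = null_fit
        tab2 = tab.copy()
        g0 = tab2.index[0]
        tab2.loc[g0, "wald_z"] = 1e6
        emp = empirical_pvalues(counts, cohort, sf=sf, B=100, seed=55,
                                table=tab2)
        n_null = 100 * int(tab2["converged"].sum())
        assert emp.loc[g0] == pytest.approx(1.0 / (n_null + 1))

    def test_range_invariant(self, null_fit):
        counts, cohort, sf, tab = null_fit
        emp = empirical_pvalues(counts, cohort, sf=sf, B=100, seed=56,
                                table=tab)
        e = emp.dropna()
        assert ((e > 0) & (e <= 1)).all()

    def test_per_gene_mode(self, null_fit):
        counts, cohort, sf, tab = null_fit
        emp = empirical_pvalues(counts, cohort, sf=sf, B=100, seed=57,
                                table=tab, pooled=False)
        e = emp.dropna()
        assert (e >= 1.0 / 101).all() and (e <= 1.0).all()

    def test_low_b_warns(self, null_fit):
        counts, cohort, sf, tab = null_fit
        with pytest.warns(UserWarning, match="unreliable"):
            empirical_pvalues(counts, cohort, sf=sf, B=50, seed=58, table=tab)


class TestCallDifferential:
    @pytest.fixture()
    def toy_table(self):
        return pd.DataFrame({
            "log2fc": [0.30, 0.20, -0.35, 0.01],
            "empirical_p": [0.04, 0.04, 0.001, 0.2],
        }, index=["a", "b", "c", "d"])

    def test_threshold_arithmetic(self, toy_table):
        genes, summary = call_differential(toy_table)
        assert "a" in genes        # 2^0.30 ~ 1.23 > 1.2, p < 0.05
        assert "b" not in genes    # 2^0.20 ~ 1.15 < 1.2
        assert summary == {"n_called": 2, "up_in_FL": 1, "down_in_FL": 1}

    def test_alternative_p_column(self, toy_table):
        toy_table["wald_p"] = [0.001, 0.5, 0.5, 0.5]
        genes, _ = call_differential(toy_table, p_col="wald_p", p_thresh=0.005)
        assert list(genes) == ["a"]


class TestCytobandEnrichment:
    def test_whole_tiny_band_near_minimal_p(self):
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "chrom": "chr1", "start": range(200), "end": range(1, 201),
            "strand": "+",
            "cytoband": ["b0"] * 3 + ["b1"] * 197,
        })
        out = cytoband_enrichment(["g0", "g1", "g2"], ann)
        expected = 1.0 / (200 * 199 * 198 / 6)  # C(3,3)/C(200,3)
        assert out.loc["b0", "p"] == pytest.approx(expected, rel=1e-6)

    def test_zero_overlap_p_one(self):
        ann = pd.DataFrame({
            "gene_id": ["g0", "g1", "g2", "g3"], "chrom": "chr1",
            "start": [0, 10, 20, 30], "end": [5, 15, 25, 35], "strand": "+",
            "cytoband": ["b0", "b0", "b1", "b1"],
        })
        out = cytoband_enrichment(["g2"], ann)
        assert out.loc["b0", "p"] == 1.0

    def test_random_draws_rarely_significant(self):
        rng = np.random.default_rng(61)
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(500)],
            "chrom": "chr1", "start": range(500), "end": range(1, 501),
            "strand": "+",
            "cytoband": rng.choice([f"b{k}" for k in range(20)], size=500),
        })
        n_sig = []
        for rep in range(20):
            picked = rng.choice(ann["gene_id"], size=25, replace=False)
            out = cytoband_enrichment(picked, ann)
            n_sig.append((out["fdr"] < 0.05).sum())
        assert np.mean(n_sig) < 0.5

    def test_bh_monotone(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()


class TestSignalConcentration:
    def test_equal_magnitudes_give_diagonal(self):
        tab = pd.DataFrame({"log2fc": [0.5] * 10})
        curve = signal_concentration(tab)
        np.testing.assert_allclose(curve["fraction_signal"],
                                   curve["fraction_genes"])

    def test_single_driver_jumps(self):
        tab = pd.DataFrame({"log2fc": [3.0] + [0.0] * 9})
        curve = signal_concentration(tab)
        assert curve.loc[1, "fraction_signal"] == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(62)
        mags = rng.exponential(size=50)
        tab = pd.DataFrame({"log2fc": mags * rng.choice([-1, 1], size=50)})
        curve = signal_concentration(tab)
        srt = np.sort(np.abs(tab["log2fc"]))[::-1]
        expected = np.concatenate([[0], np.cumsum(srt) / srt.sum()])
        np.testing.assert_allclose(curve["fraction_signal"], expected)
        # concave, monotone
        assert (np.diff(curve["fraction_signal"]) >= -1e-12).all()
        assert (np.diff(np.diff(curve["fraction_signal"])) <= 1e-12).all()
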