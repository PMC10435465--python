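"""Normalization, NB differential testing and effect-size estimators."""

import numpy as np
import pandas as pd
import pytest

from locusarch.expression import (
    ddct,
    differential_expression,
    fold_change,
    mrna_fraction,
    percent_reduction,
    size_factors,
)
from oracles import reference_bh


def nb_counts(rng, mu, n_samples, dispersion=0.05, prefix="s"):
    n = 1.0 / dispersion
    mat = rng.negative_binomial(n, n / (n + np.asarray(mu)[:, None]),
                                (len(mu), n_samples))
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(len(mu))],
        columns=[f"{prefix}{j}" for j in range(n_samples)],
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_has_double_factor(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [10, 20, 30], "c": [20, 40, 60]}
        )
        sf = size_factors(counts)
        assert sf["c"] / sf["a"] == pytest.approx(2.0)
        assert sf["a"] == pytest.approx(sf["b"])
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_single_sample_is_unit(self):
        assert size_factors(pd.DataFrame({"a": [5, 9]}))["a"] == 1.0

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = nb_counts(rng, rng.uniform(10, 1000, 50), 4)
        perm = counts.sample(frac=1, random_state=1)
        pd.testing.assert_series_equal(size_factors(counts), size_factors(perm))

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(4)
        counts = nb_counts(rng, rng.uniform(10, 1000, 50), 4)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 3
        r0 = size_factors(scaled) / size_factors(counts)
        assert r0["s0"] / r0["s1"] == pytest.approx(3.0, rel=1e-6)

    def test_fallback_warns_without_allpositive_gene(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(UserWarning):
            sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_deseq2_median_of_ratios(self):
        # independent oracle: pydeseq2's size-factor fit; factors agree up to
        # the geometric-mean rescaling applied here
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(8)
        counts = nb_counts(rng, rng.uniform(20, 2000, 80), 6)
        meta = pd.DataFrame(
            {"condition": ["x"] * 3 + ["y"] * 3}, index=counts.columns
        )
        dds = pydeseq2.DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        theirs = pd.Series(dds.obs["size_factors"].to_numpy(), index=counts.columns)
        ratio = size_factors(counts) / theirs
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-6)


class TestDifferentialExpression:
    A = [f"a{j}" for j in range(4)]
    B = [f"b{j}" for j in range(4)]

    def simulate(self, seed, mu_a, mu_b, dispersion=0.05):
        rng = np.random.default_rng(seed)
        ca = nb_counts(rng, mu_a, 4, dispersion, prefix="a")
        cb = nb_counts(rng, mu_b, 4, dispersion, prefix="b")
        return pd.concat([ca, cb], axis=1)

    def test_prefilter_excludes_low_count_genes(self):
        counts = pd.DataFrame(
            {s: [1, 500] for s in self.A} | {s: [1, 500] for s in self.B},
            index=["low", "high"],
        )
        counts.loc["low"] = [2, 1, 1, 1, 1, 1, 1, 1]  # 9 reads total
        de = differential_expression(counts, self.A, self.B)
        assert bool(de.loc["low", "excluded"])
        assert np.isnan(de.loc["low", "pvalue"])
        assert not de.loc["high", "excluded"]

    def test_group_size_validation(self):
        counts = pd.DataFrame({s: [10] for s in self.A + self.B})
        with pytest.raises(ValueError):
            differential_expression(counts, self.A[:1], self.B)

    def test_label_swap_negates_lfc_and_keeps_p(self):
        mu = np.random.default_rng(6).uniform(20, 2000, 60)
        counts = self.simulate(7, mu, mu * 1.5)
        fwd = differential_expression(counts, self.A, self.B)
        rev = differential_expression(counts, self.B, self.A)
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"])
        np.testing.assert_allclose(
            fwd["pvalue"].dropna(), rev["pvalue"].dropna()
        )

    def test_padj_matches_reference_step_up(self):
        mu = np.random.default_rng(9).uniform(20, 2000, 120)
        counts = self.simulate(10, mu, mu)
        de = differential_expression(counts, self.A, self.B)
        tested = de[~de["excluded"]]
        np.testing.assert_allclose(
            tested["padj"], reference_bh(tested["pvalue"].to_numpy())
        )
        assert (tested["padj"] >= tested["pvalue"] - 1e-12).all()
        assert tested["padj"].between(0, 1).all()

    def test_type_one_error_calibrated(self):
        # identical groups: the fraction of raw p-values below 0.05 should
        # sit near the nominal level across many null simulations
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            mu = rng.uniform(50, 5000, 100)
            counts = self.simulate(int(rng.integers(2**31)), mu, mu)
            de = differential_expression(counts, self.A, self.B)
            pvals.append(de.loc[~de["excluded"], "pvalue"].to_numpy())
        frac = (np.concatenate(pvals) < 0.05).mean()
        assert 0.025 <= frac <= 0.085

    def test_large_effect_is_detected(self):
        mu = np.full(50, 200.0)
        mu_b = mu.copy()
        mu_b[0] = 200.0 * 100  # 100-fold induction of one gene
        counts = self.simulate(12, mu, mu_b)
        de = differential_expression(counts, self.A, self.B)
        assert de.loc["g0", "padj"] < 0.05
        assert de.loc["g0", "log2_fc"] > np.log2(50)


class TestEffectReadouts:
    def de_with_means(self, m_wt, m_mut, gene="g"):
        return pd.DataFrame(
            {
                "gene": [gene],
                "base_mean_a": [m_wt],
                "base_mean_b": [m_mut],
                "log2_fc": [0.0],
                "pvalue": [1.0],
                "padj": [1.0],
                "excluded": [False],
            }
        ).set_index("gene", drop=False)

    def test_equal_means_zero_reduction(self):
        assert percent_reduction(self.de_with_means(100, 100), "g") == 0.0

    def test_arithmetic_example(self):
        assert round(percent_reduction(self.de_with_means(100, 7), "g")) == 93

    def test_twofold_increase_is_negative(self):
        de = self.de_with_means(100, 200.5)
        assert percent_reduction(de, "g") == pytest.approx(-100.0)
        assert fold_change(de, "g") == pytest.approx(2.0)

    def test_untested_gene_is_missing(self):
        de = self.de_with_means(100, 7)
        de["excluded"] = True
        assert percent_reduction(de, "g") is None
        assert percent_reduction(de, "absent") is None


class TestMrnaFraction:
    COUNTS = pd.DataFrame(
        {"s1": [50, 30, 20], "s2": [10, 60, 30]}, index=["a", "b", "c"]
    )

    def test_all_genes_is_unity(self):
        _, mean = mrna_fraction(self.COUNTS, ["a", "b", "c"])
        assert mean == pytest.approx(1.0)

    def test_half_library(self):
        frac, mean = mrna_fraction(self.COUNTS, ["a", "b"])
        assert frac["s1"] == pytest.approx(0.8)
        assert frac["s2"] == pytest.approx(0.7)
        assert mean == pytest.approx(0.75)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            mrna_fraction(self.COUNTS, [])


class TestDdct:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])

    def test_sample_identical_to_calibrator(self):
        t = self.table([
            ("w1", "WT", "Csn2", 20.0), ("w1", "WT", "Gapdh", 15.0),
            ("m1", "MUT", "Csn2", 20.0), ("m1", "MUT", "Gapdh", 15.0),
        ])
        out = ddct(t, "Csn2", calibrator_group="WT")
        np.testing.assert_allclose(out["relative_expression"], 1.0)

    def test_one_cycle_is_twofold(self):
        t = self.table([
            ("w1", "WT", "Csn2", 20.0), ("w1", "WT", "Gapdh", 15.0),
            ("m1", "MUT", "Csn2", 21.0), ("m1", "MUT", "Gapdh", 15.0),
        ])
        out = ddct(t, "Csn2", calibrator_group="WT").set_index("sample")
        assert out.loc["m1", "relative_expression"] == pytest.approx(0.5)

    def test_closed_form_example(self):
        t = self.table([
            ("w1", "WT", "Csn2", 20.0), ("w1", "WT", "Gapdh", 15.0),
            ("m1", "MUT", "Csn2", 25.0), ("m1", "MUT", "Gapdh", 15.0),
        ])
        out = ddct(t, "Csn2", calibrator_group="WT").set_index("sample")
        assert out.loc["m1", "relative_expression"] == pytest.approx(0.03125)

    def test_missing_ct_skipped_with_warning(self):
        t = self.table([
            ("w1", "WT", "Csn2", 20.0), ("w1", "WT", "Gapdh", 15.0),
            ("m1", "MUT", "Gapdh", 15.0),
        ])
        with pytest.warns(UserWarning):
            out = ddct(t, "Csn2", calibrator_group="WT")
        assert list(out["sample"]) == ["w1"]

    def test_missing_reference_gene_rejected(self):
        t = self.table([("w1", "WT", "Csn2", 20.0)])
        with pytest.raises(ValueError):
            ddct(t, "Csn2")
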