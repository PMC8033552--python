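"""Tests of gene-level summaries: SNP density, class enrichment, gene
ranking, translation efficiency, and the TE fold-change regression."""

import numpy as np
import pandas as pd
import pytest

from synoribo.genes import (
    TEFoldChangeRegression,
    class_enrichment,
    minmax_scale_signed,
    rpkm,
    snp_density,
    te_regression,
    top_genes,
    translation_efficiency,
)
from synoribo.simulate import simulate_gene_class_counts, simulate_te_table


class TestSnpDensity:
    def test_three_variants_per_1500nt_is_two_per_kb(self):
        assert snp_density(3, 1500) == pytest.approx(2.0)

    def test_zero_variants_is_zero(self):
        assert snp_density(0, 1500) == 0.0

    def test_fixture_two_variants_per_600nt(self):
        assert snp_density(2, 600) == pytest.approx(10 / 3)

    def test_linear_in_count_inverse_in_length(self):
        assert snp_density(6, 1500) == pytest.approx(2 * snp_density(3, 1500))
        assert snp_density(3, 3000) == pytest.approx(snp_density(3, 1500) / 2)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            snp_density(1, 0)


def summaries_from_counts(g: pd.DataFrame) -> pd.DataFrame:
    out = g.copy()
    out["snp_density_opt"] = 1000.0 * out["n_optimal_syn"] / out["cds_len"]
    out["snp_density_nonopt"] = 1000.0 * out["n_nonoptimal_syn"] / out["cds_len"]
    return out


class TestClassEnrichment:
    def test_programmed_enrichment_detected(self):
        rng = np.random.default_rng(30)
        g = simulate_gene_class_counts(240, 242, 500, 1.0, 3.0, 3.0, (300, 2400), rng)
        res = class_enrichment(summaries_from_counts(g))
        opt = res.comparisons["optimal_onco_vs_tsg"]
        non = res.comparisons["nonoptimal_onco_vs_tsg"]
        assert opt["direction"] == "oncogene>TSG" and opt["p_value"] < 0.05
        assert non["direction"] == "TSG>oncogene" and non["p_value"] < 0.05

    def test_identical_density_vectors_give_ks_p_one(self):
        g = pd.DataFrame({
            "gene": [f"g{i}" for i in range(40)],
            "class": ["oncogene"] * 10 + ["TSG"] * 10 + ["other"] * 20,
            "cds_len": 1000,
            "n_optimal_syn": 2,
            "n_nonoptimal_syn": 2,
        })
        res = class_enrichment(summaries_from_counts(g))
        assert res.comparisons["optimal_onco_vs_tsg"]["p_value"] == pytest.approx(1.0)
        assert res.comparisons["other_opt_vs_nonopt"]["p_value"] == pytest.approx(1.0)

    def test_empty_class_raises(self):
        g = pd.DataFrame({
            "gene": ["a", "b"], "class": ["oncogene", "other"],
            "cds_len": [900, 900], "n_optimal_syn": [1, 1], "n_nonoptimal_syn": [0, 0],
        })
        with pytest.raises(ValueError, match="insufficient"):
            class_enrichment(summaries_from_counts(g))


class TestTopGenes:
    SUMM = summaries_from_counts(pd.DataFrame({
        "gene": ["g1", "g2", "g3", "g4"],
        "class": ["oncogene"] * 4,
        "cds_len": [1000, 1000, 1000, 2000],
        "n_optimal_syn": [2, 5, 1, 4],
        "n_nonoptimal_syn": [0, 0, 0, 0],
    }))

    def test_ranked_by_density_descending(self):
        summ = summaries_from_counts(pd.DataFrame({
            "gene": ["g1", "g2", "g3"],
            "class": ["oncogene"] * 3,
            "cds_len": [1000, 1000, 1000],
            "n_optimal_syn": [2, 5, 1],  # densities 2.0, 5.0, 1.0 per kb
            "n_nonoptimal_syn": [0, 0, 0],
        }))
        got = top_genes(summ, "oncogene", "optimal", k=2)
        assert list(got["gene"]) == ["g2", "g1"]

    def test_tie_broken_by_raw_count(self):
        # g1 (2/1000) and g4 (4/2000) tie at 2.0 per kb; g4 has more SNPs
        got = top_genes(self.SUMM, "oncogene", "optimal", k=3)
        assert list(got["gene"]) == ["g2", "g4", "g1"]

    def test_k_larger_than_class_returns_full_class(self):
        got = top_genes(self.SUMM, "oncogene", "optimal", k=100)
        assert len(got) == 4

    def test_k_below_one_raises(self):
        with pytest.raises(ValueError):
            top_genes(self.SUMM, "oncogene", "optimal", k=0)


class TestTranslationEfficiency:
    def test_rpkm_formula(self):
        assert rpkm(np.array([100]), [1000], 1e6)[0] == pytest.approx(100.0)

    def test_equal_rpkms_give_te_one(self):
        te = translation_efficiency([100], [100], [1000], 1e6, 1e6)
        assert te[0] == pytest.approx(1.0)

    def test_te_quarter(self):
        # RPF RPKM 50 vs RNA RPKM 200
        te = translation_efficiency([200], [50], [1000], 1e6, 1e6)
        assert te[0] == pytest.approx(0.25)

    def test_te_invariant_to_common_scaling(self):
        te1 = translation_efficiency([120], [60], [1500], 2e6, 3e6)
        te2 = translation_efficiency([1200], [600], [1500], 2e7, 3e7)
        assert te1[0] == pytest.approx(te2[0])

    def test_zero_mrna_gives_nan(self):
        te = translation_efficiency([0], [50], [1000], 1e6, 1e6)
        assert np.isnan(te[0])

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="negative"):
            rpkm(np.array([-1]), [1000], 1e6)

    def test_fixture_te_matches_hand_computed(self, fixture_ds):
        gc = fixture_ds.gene_counts
        lens = [630, 330, 360]
        te_n = translation_efficiency(gc["rna_normal"], gc["rpf_normal"], lens, 1e6, 1e6)
        te_t = translation_efficiency(gc["rna_tumor"], gc["rpf_tumor"], lens, 1e6, 1e6)
        np.testing.assert_allclose(te_n, [2.0, 0.5, 1.0])
        np.testing.assert_allclose(te_t, [4.0, 0.25, 1.0])


class TestRegression:
    def test_scaling_maps_extremes_to_unit_interval(self):
        x = minmax_scale_signed(np.array([3.0, 5.0, 9.0]))
        assert x.min() == pytest.approx(-1.0)
        assert x.max() == pytest.approx(1.0)

    def test_effect_signs_recovered(self):
        rng = np.random.default_rng(40)
        t = simulate_te_table(1000, 0.5, -0.5, 0.1, rng)
        reg = te_regression(t)
        assert reg.coef_["n_optimal_syn"] > 0
        assert reg.coef_["n_nonoptimal_syn"] < 0
        assert reg.pvalues_["n_optimal_syn"] < 0.01
        assert reg.pvalues_["n_nonoptimal_syn"] < 0.01

    def test_design_matrix_scaled_to_signed_unit_range(self):
        rng = np.random.default_rng(41)
        t = simulate_te_table(200, 0.5, -0.5, 0.1, rng)
        reg = te_regression(t)
        exog = reg.result_.model.exog[:, 1:]  # drop intercept
        assert exog.min() >= -1.0 - 1e-12 and exog.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(exog.min(axis=0), -1.0)
        np.testing.assert_allclose(exog.max(axis=0), 1.0)

    def test_response_duplicated_as_predictor_dominates(self):
        rng = np.random.default_rng(42)
        n = 300
        y = rng.normal(0, 1, n)
        X = pd.DataFrame({"y_copy": y, "noise": rng.normal(0, 1, n)})
        reg = TEFoldChangeRegression(predictors=("y_copy", "noise")).fit(X, y)
        # scaled x' = 2(y-min)/span - 1, so the coefficient is span/2
        span = y.max() - y.min()
        assert reg.coef_["y_copy"] == pytest.approx(span / 2, rel=1e-6)
        assert abs(reg.coef_["noise"]) < 1e-6

    def test_rank_deficient_design_names_collinear_predictors(self):
        rng = np.random.default_rng(43)
        n = 200
        a = rng.normal(0, 1, n)
        X = pd.DataFrame({"a": a, "b": 2 * a + 1, "c": rng.normal(0, 1, n)})
        with pytest.raises(ValueError, match="collinear") as err:
            TEFoldChangeRegression(predictors=("a", "b", "c")).fit(X, rng.normal(0, 1, n))
        assert "a" in str(err.value) and "b" in str(err.value)

    def test_too_few_genes_raise(self):
        rng = np.random.default_rng(44)
        t = simulate_te_table(30, 0.5, -0.5, 0.1, rng)
        with pytest.raises(ValueError, match="complete genes"):
            te_regression(t)

    def test_null_covariates_stay_within_two_se(self):
        rng = np.random.default_rng(45)
        hits = total = 0
        for _ in range(20):
            t = simulate_te_table(500, 0.5, -0.5, 0.1, rng)
            reg = te_regression(t)
            for cov in ("gene_length", "dn", "expression", "gc_content"):
                total += 1
                hits += abs(reg.coef_[cov]) < 2 * reg.bse_[cov]
        assert hits / total >= 0.9
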