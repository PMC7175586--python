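import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgpde import (
    ExpressionMatrix,
    SimConfig,
    compare_models,
    fit_nb_de,
    run_preprocess,
    simulate_bulk,
    size_factors,
)

COVS = ["sex", "age", "pmi", "rin", "batch"]


def _em(values):
    g, s = np.asarray(values).shape
    return ExpressionMatrix(
        np.asarray(values, float),
        [f"g{i}" for i in range(g)],
        [f"s{i}" for i in range(s)],
        "counts",
    )


class TestSizeFactors:
    def test_doubled_library_doubles_factor(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 50).astype(float) + 1
        m = _em(np.column_stack([col, 2 * col]))
        sf = size_factors(m)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        col = np.arange(1.0, 31.0)
        m = _em(np.column_stack([col] * 4))
        np.testing.assert_allclose(size_factors(m), 1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(1)
        values = rng.poisson(80, size=(40, 6)).astype(float) + 1
        sf = size_factors(_em(values))
        # brute force: per sample, median of count/geometric-mean over genes
        loggeo = np.log(values).mean(axis=1)
        raw = np.array(
            [np.median(values[:, s] / np.exp(loggeo)) for s in range(6)]
        )
        expected = raw / stats.gmean(raw)
        np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-12)

    def test_no_all_nonzero_gene_rejected(self):
        values = np.ones((3, 2))
        values[:, 0] = 0
        with pytest.raises(ValueError, match="pre-filter"):
            size_factors(_em(values))


class TestFitNbDe:
    def test_planted_lfc_recovered_with_power(self, tiny=None):
        """Planted log2 fold changes of 2 at n=13/13 are essentially always
        recovered at FDR < 0.05."""
        recovered, total = 0, 0
        for seed in (0, 1):
            cfg = SimConfig(
                seed=seed, composition_shift={}, n_regulatory_de=50, regulatory_lfc=2.0
            )
            expr, samples, _, _, truth = simulate_bulk(cfg)
            filtered, _ = run_preprocess(expr)
            de = fit_nb_de(filtered, samples, covariates=COVS)
            planted = [g for g in truth.regulatory_lfc.index if g in set(filtered.gene_ids)]
            sig = set(de.significant())
            recovered += len(sig & set(planted))
            total += len(planted)
        assert recovered / total >= 0.8

    def test_lfc_sign_matches_planted_direction(self):
        cfg = SimConfig(seed=5, composition_shift={}, n_regulatory_de=50, regulatory_lfc=2.0)
        expr, samples, _, _, truth = simulate_bulk(cfg)
        filtered, _ = run_preprocess(expr)
        de = fit_nb_de(filtered, samples, covariates=COVS)
        planted = truth.regulatory_lfc[
            [g for g in truth.regulatory_lfc.index if g in set(filtered.gene_ids)]
        ]
        est = de.table.loc[planted.index, "lfc"]
        agree = (np.sign(est) == np.sign(planted)).mean()
        assert agree > 0.95
        # estimated magnitude near truth on average
        assert est[planted > 0].mean() == pytest.approx(2.0, abs=0.4)

    def test_group_encoding_flip_negates_lfc_keeps_p(self, null_cohort):
        expr, samples, *_ = null_cohort
        filtered, _ = run_preprocess(expr)
        sub = filtered.subset_genes(filtered.gene_ids[:150])
        de = fit_nb_de(sub, samples, covariates=["sex", "age"], independent_filtering=False)
        flipped = samples.copy()
        flipped["group"] = (
            samples["group"].astype(str).map({"case": "control", "control": "case"})
        )
        from mgpde.io import validate_sample_table

        flipped = validate_sample_table(flipped.reset_index(drop=True))
        de_f = fit_nb_de(sub, flipped, covariates=["sex", "age"], independent_filtering=False)
        np.testing.assert_allclose(de.table["lfc"], -de_f.table["lfc"], atol=1e-6)
        np.testing.assert_allclose(de.table["p"], de_f.table["p"], atol=1e-8)

    def test_size_factor_invariance_of_lfc(self, null_cohort):
        expr, samples, *_ = null_cohort
        filtered, _ = run_preprocess(expr)
        sub = filtered.subset_genes(filtered.gene_ids[:120])
        de = fit_nb_de(sub, samples, covariates=["sex"], independent_filtering=False)
        scaled_values = sub.values.copy()
        scaled_values[:, 0] *= 3.0
        scaled = ExpressionMatrix(scaled_values, sub.gene_ids, sub.sample_ids, "counts")
        de_s = fit_nb_de(scaled, samples, covariates=["sex"], independent_filtering=False)
        # the raw factor triples; the geometric-mean-1 renormalization then
        # divides every factor by 3**(1/n)
        n = sub.n_samples
        assert de_s.size_factors.iloc[0] / de.size_factors.iloc[0] == pytest.approx(
            3.0 ** ((n - 1) / n), rel=1e-6
        )
        np.testing.assert_allclose(de.table["lfc"], de_s.table["lfc"], atol=0.02)

    def test_bh_fdr_matches_step_up_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200) ** 2
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests(p, method="fdr_bh")[1]
        # ten-line independent step-up implementation
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        monotone = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(monotone, 1.0)
        np.testing.assert_allclose(fdr, expected, rtol=1e-12)

    def test_fdr_at_least_p_and_sign_convention(self, default_cohort):
        expr, samples, *_ = default_cohort
        filtered, _ = run_preprocess(expr)
        de = fit_nb_de(filtered, samples, covariates=COVS)
        t = de.table.dropna(subset=["p", "fdr"])
        assert (t["fdr"] >= t["p"] - 1e-12).all()
        assert de.model_tag == "covariates_only"

    def test_noise_mgp_covariate_does_not_inflate_type_one_error(self, null_cohort):
        expr, samples, *_ = null_cohort
        filtered, _ = run_preprocess(expr)
        rng = np.random.default_rng(13)
        noise_scores = pd.DataFrame(
            {"noise": rng.normal(size=filtered.n_samples)}, index=filtered.sample_ids
        )
        de = fit_nb_de(
            filtered,
            samples,
            covariates=COVS,
            mgp_scores=noise_scores,
            mgp_covariates=["noise"],
            independent_filtering=False,
        )
        p = de.table["p"].dropna()
        rate = (p < 0.05).mean()
        ci = 1.96 * np.sqrt(0.05 * 0.95 / len(p))
        # genes share samples, so allow twice the iid binomial half-width
        assert rate <= 0.05 + 2 * ci

    def test_rank_deficient_design_rejected(self, null_cohort):
        expr, samples, *_ = null_cohort
        sub = expr.subset_genes(expr.gene_ids[:50])
        bad = samples.copy()
        bad["pmi"] = bad["age"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_nb_de(sub, bad, covariates=["age", "pmi"])

    def test_agrees_with_independent_nb_wald_implementation(self):
        """Cross-check the vectorized NB engine against pydeseq2 on a small
        simulated cohort: rank agreement of LFC and Wald statistics."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimConfig(
            seed=11, composition_shift={}, n_regulatory_de=40, regulatory_lfc=1.5,
            n_genes=500,
        )
        expr, samples, *_ = simulate_bulk(cfg)
        filtered, _ = run_preprocess(expr)
        de = fit_nb_de(
            filtered, samples, covariates=["sex", "age"], independent_filtering=False
        )
        meta = samples.loc[filtered.sample_ids, ["group", "sex", "age"]].copy()
        meta["group"] = meta["group"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=filtered.to_frame().T.astype(int),
                metadata=meta,
                design="~sex + age + group",
                quiet=True,
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["group", "case", "control"], quiet=True)
            ds.summary()
        res = ds.results_df
        r_lfc = stats.spearmanr(de.table.loc[res.index, "lfc"], res["log2FoldChange"]).statistic
        r_stat = stats.spearmanr(de.table.loc[res.index, "wald_stat"], res["stat"]).statistic
        assert r_lfc > 0.95 and r_stat > 0.95


class TestCompareModels:
    def test_equal_inputs_fully_overlap(self, default_cohort):
        expr, samples, *_ = default_cohort
        filtered, _ = run_preprocess(expr)
        de = fit_nb_de(filtered, samples, covariates=["sex", "age"])
        out = compare_models(de, de)
        assert out["n_both"] == out["n_sig_0"] == out["n_sig_ct"]

    def test_intersection_matches_set_oracle(self, default_cohort):
        expr, samples, *_ = default_cohort
        filtered, _ = run_preprocess(expr)
        de0 = fit_nb_de(filtered, samples, covariates=["sex", "age"])
        de1 = fit_nb_de(filtered, samples, covariates=COVS)
        out = compare_models(de0, de1)
        assert out["n_both"] == len(set(out["genes_0"]) & set(out["genes_ct"]))
        assert set(out["genes_both"]) == set(out["genes_0"]) & set(out["genes_ct"])

    def test_mismatched_universe_rejected(self, default_cohort):
        expr, samples, *_ = default_cohort
        filtered, _ = run_preprocess(expr)
        de0 = fit_nb_de(filtered, samples, covariates=["sex"])
        de1 = fit_nb_de(
            filtered.subset_genes(filtered.gene_ids[:50]), samples, covariates=["sex"]
        )
        with pytest.raises(ValueError, match="universe"):
            compare_models(de0, de1)
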