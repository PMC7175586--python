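import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgpde import (
    ExpressionMatrix,
    SimConfig,
    compare_marker_sets,
    cpm_transform,
    estimate_mgp,
    estimate_mgp_once,
    mgp_group_test,
    run_preprocess,
    simulate_bulk,
)
from mgpde.io import GeneSet, GeneSetCollection, validate_sample_table

COVS = ["sex", "age", "pmi", "rin", "batch"]


def _log2cpm_from(values):
    g, s = values.shape
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(g)], [f"s{i}" for i in range(s)], unit="log2cpm"
    )


def _samples(n_case, n_control):
    n = n_case + n_control
    rng = np.random.default_rng(0)
    return validate_sample_table(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "group": ["case"] * n_case + ["control"] * n_control,
                "sex": rng.choice(["M", "F"], n),
                "age": rng.uniform(55, 90, n).round(1),
                "pmi": rng.uniform(3, 25, n).round(1),
                "rin": rng.uniform(3, 9, n).round(2),
                "batch": rng.choice(["b1", "b2"], n),
            }
        )
    )


class TestEstimateOnce:
    def test_rank_one_recovers_hidden_factor(self):
        rng = np.random.default_rng(1)
        pi = rng.uniform(0.1, 0.9, size=12)
        loadings = rng.uniform(0.5, 2.0, size=8)
        values = np.outer(loadings, pi)
        m = _log2cpm_from(values)
        scores, _ = estimate_mgp_once(m, set(m.gene_ids))
        r = stats.pearsonr(scores, pi).statistic
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_antagonistic_markers_get_opposite_loadings(self):
        rng = np.random.default_rng(2)
        pi = rng.uniform(0, 1, size=10)
        values = np.vstack([pi, -pi + 1.0, pi * 2.0])
        m = _log2cpm_from(values)
        _, loadings = estimate_mgp_once(m, set(m.gene_ids))
        assert np.sign(loadings["g0"]) == np.sign(loadings["g2"])
        assert np.sign(loadings["g1"]) == -np.sign(loadings["g0"])
        # majority of loadings positive by the orientation convention
        assert (loadings > 0).sum() >= 2

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        pi = rng.uniform(0, 1, size=15)
        values = pi[None, :] + rng.normal(0, 0.05, size=(10, 15))
        m = _log2cpm_from(values)
        scores, _ = estimate_mgp_once(m, set(m.gene_ids))
        # oracle: eigendecomposition of the covariance of z-scored markers
        z = (values - values.mean(1, keepdims=True)) / values.std(1, ddof=1, keepdims=True)
        X = z.T - z.T.mean(0, keepdims=True)
        w, v = np.linalg.eigh(np.cov(X.T))
        pc1 = X @ v[:, -1]
        r = abs(stats.pearsonr(scores, pc1).statistic)
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_too_few_markers_rejected(self):
        m = _log2cpm_from(np.random.default_rng(0).normal(size=(5, 6)))
        with pytest.raises(ValueError, match="2 usable markers"):
            estimate_mgp_once(m, {"g0"})

    def test_zero_variance_marker_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(4, 8))
        values[2] = 3.14
        m = _log2cpm_from(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            _, loadings = estimate_mgp_once(m, set(m.gene_ids))
        assert "g2" not in loadings.index


class TestEstimateMgp:
    def _rank_one_setup(self, n=14, n_markers=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        pi = rng.uniform(0.2, 0.8, size=n)
        loadings = rng.uniform(0.5, 1.5, size=n_markers)
        values = np.outer(loadings, pi) + rng.normal(0, noise, size=(n_markers, n))
        m = _log2cpm_from(values)
        markers = GeneSetCollection([GeneSet("ct", "ct", list(m.gene_ids))], kind="marker")
        return m, markers, _samples(n // 2, n - n // 2), pi

    def test_noise_free_subsampling_equals_full_data(self):
        m, markers, samples, pi = self._rank_one_setup()
        res = estimate_mgp(m, markers, samples, n_subsamples=30, seed=1)
        full, _ = estimate_mgp_once(m, set(m.gene_ids))
        r = abs(stats.pearsonr(res.scores["ct"], full).statistic)
        assert r == pytest.approx(1.0, abs=1e-6)
        assert abs(stats.pearsonr(res.scores["ct"], pi).statistic) > 0.999

    def test_same_seed_identical_different_seed_close(self):
        m, markers, samples, _ = self._rank_one_setup()
        a = estimate_mgp(m, markers, samples, n_subsamples=20, seed=5)
        b = estimate_mgp(m, markers, samples, n_subsamples=20, seed=5)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        c = estimate_mgp(m, markers, samples, n_subsamples=20, seed=6)
        rho = stats.spearmanr(a.scores["ct"], c.scores["ct"]).statistic
        assert rho >= 0.99

    def test_score_columns_standardized_and_sign_convention(self, default_cohort):
        expr, samples, markers, _, truth = default_cohort
        filtered, _ = run_preprocess(expr)
        log2cpm = cpm_transform(filtered, log2=True)
        res = estimate_mgp(log2cpm, markers, samples, n_subsamples=30, seed=2)
        for ct in res.cell_types:
            col = res.scores[ct].to_numpy()
            assert col.mean() == pytest.approx(0.0, abs=1e-10)
            assert col.std(ddof=1) == pytest.approx(1.0, rel=1e-10)
            # positive correlation with mean z-scored retained-marker expression
            sub = log2cpm.subset_genes(res.retained_markers[ct])
            z = (sub.values - sub.values.mean(1, keepdims=True)) / sub.values.std(
                1, ddof=1, keepdims=True
            )
            assert stats.pearsonr(col, z.mean(0)).statistic > 0

    def test_retained_markers_subset_of_input(self, default_cohort):
        expr, samples, markers, _, _ = default_cohort
        filtered, _ = run_preprocess(expr)
        log2cpm = cpm_transform(filtered, log2=True)
        res = estimate_mgp(log2cpm, markers, samples, n_subsamples=20, seed=3)
        for ct in res.cell_types:
            assert set(res.retained_markers[ct]) <= set(markers[ct].gene_ids)
            assert set(res.retained_markers[ct]) <= set(log2cpm.gene_ids)
            assert 0 < res.var_explained[ct] <= 1

    def test_recovers_true_proportions(self, default_cohort):
        expr, samples, markers, _, truth = default_cohort
        filtered, _ = run_preprocess(expr)
        log2cpm = cpm_transform(filtered, log2=True)
        res = estimate_mgp(log2cpm, markers, samples, n_subsamples=100, seed=4)
        for ct in res.cell_types:
            rho = stats.spearmanr(
                res.scores[ct], truth.proportions.loc[log2cpm.sample_ids, ct]
            ).statistic
            assert rho >= 0.8, f"{ct}: rho={rho:.3f}"

    def test_common_scaling_invariance(self):
        m, markers, samples, _ = self._rank_one_setup(noise=0.05)
        res1 = estimate_mgp(m, markers, samples, n_subsamples=15, seed=7)
        scaled = ExpressionMatrix(m.values * 37.0, m.gene_ids, m.sample_ids, "log2cpm")
        res2 = estimate_mgp(scaled, markers, samples, n_subsamples=15, seed=7)
        np.testing.assert_allclose(res1.scores.to_numpy(), res2.scores.to_numpy(), atol=1e-8)

    def test_median_robust_to_contaminated_samples(self):
        m, markers, samples, pi = self._rank_one_setup(n=20, noise=0.02, seed=8)
        res_clean = estimate_mgp(m, markers, samples, n_subsamples=60, seed=9)
        corrupted = m.values.copy()
        corrupted[:4, :2] += 50.0  # gross outliers in <=10% of samples
        res_dirty = estimate_mgp(
            ExpressionMatrix(corrupted, m.gene_ids, m.sample_ids, "log2cpm"),
            markers,
            samples,
            n_subsamples=60,
            seed=9,
        )
        rho_clean = abs(stats.spearmanr(res_clean.scores["ct"], pi).statistic)
        rho_dirty = abs(stats.spearmanr(res_dirty.scores["ct"], pi).statistic)
        assert abs(rho_clean - rho_dirty) < 0.05

    def test_tiny_group_rejected(self):
        m, markers, _, _ = self._rank_one_setup()
        samples = _samples(1, 13)
        with pytest.raises(ValueError, match="at least 2"):
            estimate_mgp(m, markers, samples, n_subsamples=5, seed=0)


class TestCompareMarkerSets:
    def test_identical_results_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(size=(15, 2)), columns=["a", "b"],
            index=[f"s{i}" for i in range(15)],
        )
        from mgpde.mgp import MGPResult

        res = MGPResult(scores, {}, {}, 10)
        table = compare_marker_sets(res, res)
        assert np.allclose(table["pearson_r"], 1.0)

    def test_split_marker_subsets_agree(self):
        # 60 markers/type so each half keeps a reliable 30-marker panel
        expr, samples, markers, _, _ = simulate_bulk(
            SimConfig(seed=200, markers_per_type=60)
        )
        filtered, _ = run_preprocess(expr)
        log2cpm = cpm_transform(filtered, log2=True)
        half_a, half_b = [], []
        for s in markers:
            present = [g for g in s.gene_ids if g in set(log2cpm.gene_ids)]
            half_a.append(GeneSet(s.set_id, s.name, present[::2]))
            half_b.append(GeneSet(s.set_id, s.name, present[1::2]))
        res_a = estimate_mgp(
            log2cpm, GeneSetCollection(half_a, kind="marker"), samples, 30, seed=1
        )
        res_b = estimate_mgp(
            log2cpm, GeneSetCollection(half_b, kind="marker"), samples, 30, seed=2
        )
        table = compare_marker_sets(res_a, res_b)
        assert (table["pearson_r"] >= 0.9).all()

    def test_disjoint_cell_types_rejected(self):
        from mgpde.mgp import MGPResult

        idx = [f"s{i}" for i in range(5)]
        a = MGPResult(pd.DataFrame({"x": np.arange(5.0)}, index=idx), {}, {}, 1)
        b = MGPResult(pd.DataFrame({"y": np.arange(5.0)}, index=idx), {}, {}, 1)
        with pytest.raises(ValueError, match="common"):
            compare_marker_sets(a, b)


class TestGroupTest:
    def test_permuted_labels_center_coefficient_at_zero(self):
        rng = np.random.default_rng(11)
        coeffs = []
        for rep in range(200):
            n = 20
            scores = pd.DataFrame(
                {"ct": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)]
            )
            from mgpde.mgp import MGPResult

            samples = _samples(10, 10)
            res = MGPResult(scores, {}, {}, 1)
            out = mgp_group_test(res, samples, covariates=["age"])
            coeffs.append(out.loc["ct", "lm_coefficient"])
        assert abs(np.mean(coeffs)) < 3 * np.std(coeffs) / np.sqrt(len(coeffs))

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        from mgpde.mgp import MGPResult

        samples = _samples(13, 13)
        hits = 0
        n_rep = 400
        for rep in range(n_rep):
            scores = pd.DataFrame(
                {"ct": rng.normal(size=26)}, index=samples.index
            )
            out = mgp_group_test(MGPResult(scores, {}, {}, 1), samples, covariates=COVS)
            hits += out.loc["ct", "wilcoxon_p"] < 0.05
        rate = hits / n_rep
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - ci <= rate <= 0.05 + ci

    def test_planted_shift_detected_with_power(self):
        """A strong oligodendrocyte excess in cases (~1.3 SD of the
        within-group composition spread) is detected by the
        covariate-adjusted Wilcoxon in >=80% of simulated cohorts."""
        hits, n_rep = 0, 25
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=seed, composition_shift={"oligodendrocyte": 0.8}, n_regulatory_de=0
            )
            expr, samples, markers, _, _ = simulate_bulk(cfg)
            filtered, _ = run_preprocess(expr)
            log2cpm = cpm_transform(filtered, log2=True)
            mgp = estimate_mgp(log2cpm, markers, samples, n_subsamples=50, seed=seed)
            out = mgp_group_test(mgp, samples, covariates=COVS)
            hits += out.loc["oligodendrocyte", "wilcoxon_p"] < 0.05
        assert hits / n_rep >= 0.8

    def test_collinear_covariates_named(self):
        from mgpde.mgp import MGPResult

        samples = _samples(6, 6).copy()
        samples["pmi"] = samples["age"] * 2.0  # aliased pair
        scores = pd.DataFrame({"ct": np.arange(12.0)}, index=samples.index)
        with pytest.raises(ValueError, match="age.*pmi|pmi.*age"):
            mgp_group_test(MGPResult(scores, {}, {}, 1), samples, covariates=["age", "pmi"])
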