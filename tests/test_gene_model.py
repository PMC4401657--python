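"""PC-regression gene model: imputation, pruning, F-test, permutation."""

import numpy as np
import pytest
from scipy import stats

import pcgsa
from pcgsa.gene_model import (
    AdaptiveSchedule,
    GeneExcluded,
    build_gene_model,
    fit_gene_regression,
    impute_missing,
    permutation_pvalue,
)

from conftest import exact_corr_pair


class TestImputeMissing:
    def test_complete_block_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(10, 4)).astype(float)
        out, kept = impute_missing(X)
        assert np.array_equal(out, X)
        assert kept.tolist() == [0, 1, 2, 3]

    def test_single_snp_falls_back_to_column_mean(self):
        X = np.array([[0.0], [1.0], [2.0], [1.0], [np.nan]])
        out, _ = impute_missing(X)
        assert out[4, 0] == pytest.approx(1.0)

    def test_perfectly_correlated_neighbour_reproduces_value(self):
        # middle SNP is an exact copy of its left neighbour (r = 1); the
        # least-squares prediction from the flanking SNP must reproduce it
        left = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        mid = left.copy()
        mid[2] = np.nan
        right = np.array([2.0, 2.0, 1.0, 0.0, 1.0])
        out, _ = impute_missing(np.column_stack([left, mid, right]))
        # hand-computed least squares on the 4 complete samples: with the
        # right column included the fit still passes through (left=2 -> 2)
        assert out[2, 1] == pytest.approx(2.0, abs=1e-8)

    def test_all_missing_column_dropped(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan], [0.0, np.nan]])
        out, kept = impute_missing(X)
        assert out.shape == (3, 1)
        assert kept.tolist() == [0]

    def test_values_stay_in_dosage_range(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(50, 5)).astype(float)
        X[rng.random(X.shape) < 0.2] = np.nan
        out, _ = impute_missing(X)
        assert np.isfinite(out).all()
        assert (out >= 0).all() and (out <= 2).all()


class TestBuildGeneModel:
    def test_perfectly_correlated_pair_collapses_to_one_pc(self):
        X = exact_corr_pair(100, 1.0)
        model = build_gene_model(X, 0.999)
        assert model.K == 1
        assert model.n_snps == 2

    def test_full_retention_keeps_all_independent_snps(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        model = build_gene_model(X, 1.0)
        assert model.K == 5

    def test_pruning_threshold_on_correlated_pair(self):
        # sample correlation exactly 0.9 -> eigenvalue shares (0.95, 0.05)
        X = exact_corr_pair(100, 0.9)
        assert build_gene_model(X, 0.999).K == 2
        assert build_gene_model(X, 0.94).K == 1

    def test_scores_orthonormal_and_eigenvalues_descending(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(80, 12)).astype(float)
        model = build_gene_model(X, 0.999)
        U = model.pc_scores
        assert np.allclose(U.T @ U, np.eye(model.K), atol=1e-8)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        assert (model.eigenvalues > 0).all()

    def test_k_bounded_by_rank(self):
        rng = np.random.default_rng(4)
        for n, m in [(5, 10), (30, 3), (10, 10)]:
            X = rng.integers(0, 3, size=(n, m)).astype(float)
            try:
                model = build_gene_model(X, 1.0)
            except GeneExcluded:
                continue
            assert 1 <= model.K <= min(n - 1, m)

    def test_monomorphic_gene_excluded(self):
        with pytest.raises(GeneExcluded, match="monomorphic"):
            build_gene_model(np.ones((20, 3)), 0.999)


class TestFitGeneRegression:
    def test_orthogonal_phenotype_gives_f_zero(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(40, 3)).astype(float)
        model = build_gene_model(X, 1.0)
        y = rng.standard_normal(40)
        basis = np.column_stack([np.ones(40) / np.sqrt(40), model.pc_scores])
        y = y - basis @ (basis.T @ y)  # orthogonal to intercept and all PCs
        fit = fit_gene_regression(model, y)
        assert fit.F == pytest.approx(0.0, abs=1e-20)
        assert fit.p == 1.0

    def test_single_pc_f_equals_squared_t(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        model = build_gene_model(x[:, None], 1.0)
        fit = fit_gene_regression(model, y)
        lr = stats.linregress(x, y)
        t2 = lr.rvalue**2 / (1 - lr.rvalue**2) * (20 - 2)
        assert fit.F == pytest.approx(t2, rel=1e-10)
        assert fit.p == pytest.approx(lr.pvalue, rel=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(60, 6)).astype(float)
        W = rng.standard_normal((60, 2))
        y = rng.standard_normal(60) + W[:, 0]
        model = build_gene_model(X, 0.999)
        fit = fit_gene_regression(model, y, covariates=W)
        full = sm.OLS(y, np.column_stack([np.ones(60), W, model.pc_scores])).fit()
        null = sm.OLS(y, np.column_stack([np.ones(60), W])).fit()
        f_sm, p_sm, _ = full.compare_f_test(null)
        assert fit.F == pytest.approx(f_sm, rel=1e-8)
        assert fit.p == pytest.approx(p_sm, rel=1e-8)

    def test_perfect_fit_reports_clipped_p(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, size=(30, 2)).astype(float)
        model = build_gene_model(X, 1.0)
        y = model.pc_scores[:, 0]
        fit = fit_gene_regression(model, y)
        assert fit.p <= 1e-100  # clipped to a representable minimum, not 0
        assert fit.p > 0

    def test_scale_and_affine_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, size=(50, 4)).astype(float)
        y = rng.standard_normal(50)
        base = fit_gene_regression(build_gene_model(X, 0.999), y)
        scaled = fit_gene_regression(build_gene_model(X, 0.999), 3.7 * y)
        X2 = X.copy()
        X2[:, 1] = -2.0 * X2[:, 1] + 5.0  # affine recode of one SNP
        recoded = fit_gene_regression(build_gene_model(X2, 0.999), y)
        assert scaled.F == pytest.approx(base.F, abs=1e-10)
        assert recoded.F == pytest.approx(base.F, abs=1e-10)
        assert recoded.p == pytest.approx(base.p, rel=1e-10)

    def test_insufficient_df_excluded(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, size=(5, 8)).astype(float)
        model = build_gene_model(X, 1.0)
        with pytest.raises(GeneExcluded, match="df"):
            fit_gene_regression(model, rng.standard_normal(5))

    def test_rank_deficient_covariates_error(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 3, size=(40, 3)).astype(float)
        model = build_gene_model(X, 0.999)
        W = np.column_stack([np.ones(40), np.ones(40)])
        with pytest.raises(ValueError, match="rank"):
            fit_gene_regression(model, rng.standard_normal(40), covariates=W)


class TestPermutationPvalue:
    def test_strong_signal_hits_floor(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 3, size=(60, 3)).astype(float)
        model = build_gene_model(X, 0.999)
        y = model.pc_scores[:, 0] + 0.01 * rng.standard_normal(60)
        sched = AdaptiveSchedule(checkpoints=(199,), min_exceedances=10)
        p, n_used = permutation_pvalue(model, y, schedule=sched, rng_seed=1)
        assert n_used == 199
        assert p == pytest.approx(1 / 200)

    def test_null_phenotype_p_not_extreme_and_deterministic(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 3, size=(80, 4)).astype(float)
        model = build_gene_model(X, 0.999)
        y = rng.standard_normal(80)
        sched = AdaptiveSchedule(checkpoints=(99, 999), min_exceedances=10)
        p1, _ = permutation_pvalue(model, y, schedule=sched, rng_seed=5)
        p2, _ = permutation_pvalue(model, y, schedule=sched, rng_seed=5)
        assert p1 == p2
        fit = fit_gene_regression(model, y)
        # permutation and asymptotic p agree loosely even at 999 permutations
        assert abs(p1 - fit.p) < 0.15

    def test_agrees_with_asymptotic_under_null(self):
        # permutation vs F-distribution p across many null genes; the two
        # should be nearly identical gene by gene (small Monte-Carlo noise)
        cfg = pcgsa.SimConfig(n_samples=300, n_genes=30, seed=21)
        ds = pcgsa.simulate_genotypes(cfg)
        y = pcgsa.simulate_null_phenotype(ds, seed=3)
        ann = pcgsa.annotate(ds.snps, pcgsa.gene_locations(cfg), 0)
        sched = AdaptiveSchedule(checkpoints=(2000,), min_exceedances=10)
        pa, pp = [], []
        for g, (gid, idx) in enumerate(ann.assignments.items()):
            block, _ = impute_missing(ds.snp_block(idx))
            model = build_gene_model(block, 0.999, gene_id=gid)
            pa.append(fit_gene_regression(model, y).p)
            pp.append(permutation_pvalue(model, y, schedule=sched, rng_seed=g)[0])
        pa, pp = np.array(pa), np.array(pp)
        assert np.max(np.abs(pa - pp)) < 0.06
        assert stats.spearmanr(pa, pp).statistic > 0.97
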