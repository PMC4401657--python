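"""Gene-level GLS tests: probit transform, self-contained, competitive, generalized."""

import numpy as np
import pytest
from scipy import stats

import pcgsa
from pcgsa.gene_model import GeneResult
from pcgsa.geneset import (
    DegenerateFit,
    GeneLevelDesign,
    competitive_test,
    design_from_results,
    generalized_test,
    multiple_testing_adjust,
    p_to_z,
    self_contained_test,
)


def identity_design(z, covariates=None):
    ids = [f"G{i}" for i in range(len(z))]
    return GeneLevelDesign(ids, np.asarray(z, float), covariates or {}, np.eye(len(z)))


class TestProbitTransform:
    def test_median_maps_to_zero(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile(self):
        assert p_to_z(0.05) == pytest.approx(1.644854, abs=1e-6)

    def test_p_one_is_clipped(self):
        assert p_to_z(1.0) == pytest.approx(stats.norm.isf(1 - 1e-12), abs=1e-9)

    def test_nonpositive_p_is_error(self):
        with pytest.raises(ValueError):
            p_to_z(0.0)
        with pytest.raises(ValueError):
            p_to_z(np.array([0.5, -0.1]))


class TestSelfContained:
    def test_unit_z_identity_r(self):
        res = self_contained_test(np.ones(4), np.eye(4))
        assert res.stat == pytest.approx(2.0, abs=1e-12)
        assert res.p_one_sided == pytest.approx(0.0227501, abs=1e-6)

    def test_zero_z_gives_half(self):
        res = self_contained_test(np.zeros(5), np.eye(5))
        assert res.stat == 0.0
        assert res.p_one_sided == pytest.approx(0.5)

    def test_matches_one_sided_z_test(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(12)
        res = self_contained_test(z, np.eye(12))
        stat = z.mean() * np.sqrt(12)
        assert res.stat == pytest.approx(stat, abs=1e-10)
        assert res.p_one_sided == pytest.approx(stats.norm.sf(stat), rel=1e-10)

    def test_perfectly_correlated_duplicate_adds_nothing(self):
        z = np.array([1.3, 1.3])
        R = np.array([[1.0, 1.0 - 1e-8], [1.0 - 1e-8, 1.0]])
        res = self_contained_test(z, R)
        single = self_contained_test(np.array([1.3]), np.eye(1))
        assert res.stat == pytest.approx(single.stat, abs=1e-3)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            self_contained_test(np.array([]), np.eye(0))


class TestCompetitive:
    def test_equals_pooled_two_sample_t(self):
        rng = np.random.default_rng(1)
        z = np.concatenate([rng.standard_normal(12) + 0.4, rng.standard_normal(30)])
        design = identity_design(z)
        res = competitive_test(design, [f"G{i}" for i in range(12)],
                               correct_size_density=False)
        t, p = stats.ttest_ind(z[:12], z[12:], equal_var=True, alternative="greater")
        assert res.stat == pytest.approx(t, abs=1e-10)
        assert res.p_one_sided == pytest.approx(p, abs=1e-10)

    def test_worked_example_two_vs_four(self):
        # with zero within-group variance the pooled t statistic is infinite;
        # the GLS flags the zero residual variance as a degenerate fit, and a
        # small within-group perturbation recovers the finite t-test oracle
        z = np.array([2.0, 2.0, 0.0, 0.0, 0.0, 0.0])
        design = identity_design(z)
        with pytest.raises(DegenerateFit):
            competitive_test(design, ["G0", "G1"], correct_size_density=False)
        z = z + np.array([0.01, -0.01, 0.02, -0.02, 0.01, -0.01])
        design = identity_design(z)
        res = competitive_test(design, ["G0", "G1"], correct_size_density=False)
        t, p = stats.ttest_ind(z[:2], z[2:], equal_var=True, alternative="greater")
        assert res.stat == pytest.approx(t, abs=1e-12)
        assert res.p_one_sided == pytest.approx(p, abs=1e-12)

    def test_identical_z_gives_half(self):
        design = identity_design(np.full(10, 0.7))
        res = competitive_test(design, ["G0", "G1", "G2"], correct_size_density=False)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.p_one_sided == pytest.approx(0.5)

    def test_all_or_none_membership_is_error(self):
        design = identity_design(np.arange(5.0))
        with pytest.raises(ValueError, match="indicator"):
            competitive_test(design, [f"G{i}" for i in range(5)])
        with pytest.raises(ValueError, match="indicator"):
            competitive_test(design, ["other"])

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        # Frisch-Waugh: a covariate orthogonal to [1, S] under the R^-1 inner
        # product does not move the set coefficient
        rng = np.random.default_rng(2)
        G = 30
        A = rng.standard_normal((G, 400))  # well-conditioned correlation matrix
        R = np.corrcoef(A)
        z = rng.standard_normal(G)
        ids = [f"G{i}" for i in range(G)]
        design = GeneLevelDesign(ids, z, {}, R)
        s = design.indicator(ids[:8])
        X1 = np.column_stack([np.ones(G), s])
        Ri = np.linalg.inv(R)
        c = rng.standard_normal(G)
        c = c - X1 @ np.linalg.solve(X1.T @ Ri @ X1, X1.T @ Ri @ c)
        base = generalized_test(design, {"set": s}, "set")
        with_cov = generalized_test(design, {"set": s, "c": c}, "set")
        assert with_cov.beta == pytest.approx(base.beta, abs=1e-8)

    def test_size_correction_columns_are_reported(self):
        rng = np.random.default_rng(3)
        G = 25
        results = [
            GeneResult(f"G{i}", "1", i * 100, i * 100 + 50,
                       n_snps=int(rng.integers(5, 15)),
                       n_params=int(rng.integers(2, 5)),
                       n_used=100, stat=1.0,
                       p=float(rng.uniform(0.01, 0.99)), z=0.0)
            for i in range(G)
        ]
        design = design_from_results(results, np.eye(G))
        res = competitive_test(design, [f"G{i}" for i in range(6)])
        assert set(res.covariates_used) == {"n_pcs", "density", "log_n_pcs", "log_density"}


class TestGeneralized:
    def test_reduces_to_competitive(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(20)
        design = identity_design(z)
        s = design.indicator([f"G{i}" for i in range(7)])
        a = competitive_test(design, [f"G{i}" for i in range(7)],
                             correct_size_density=False)
        b = generalized_test(design, {"set": s}, "set")
        assert (a.beta, a.se, a.stat, a.p_one_sided) == (b.beta, b.se, b.stat, b.p_one_sided)

    def test_perfect_fit_is_degenerate(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(15)
        design = identity_design(z)
        with pytest.raises(DegenerateFit):
            generalized_test(design, {"z_copy": z.copy()}, "z_copy")

    def test_joint_disjoint_sets_match_marginal_fits(self):
        rng = np.random.default_rng(6)
        G = 400
        z = rng.standard_normal(G)
        design = identity_design(z)
        ids = design.gene_ids
        s1 = design.indicator(ids[:40])
        s2 = design.indicator(ids[60:100])
        joint1 = generalized_test(design, {"s1": s1, "s2": s2}, "s1")
        joint2 = generalized_test(design, {"s1": s1, "s2": s2}, "s2")
        marg1 = generalized_test(design, {"s1": s1}, "s1")
        marg2 = generalized_test(design, {"s2": s2}, "s2")
        assert abs(joint1.beta - marg1.beta) < 2 * marg1.se
        assert abs(joint2.beta - marg2.beta) < 2 * marg2.se

    def test_unknown_tested_column_is_error(self):
        design = identity_design(np.arange(4.0))
        with pytest.raises(ValueError, match="not in formula"):
            generalized_test(design, {"a": np.ones(4)}, "b")


class TestMultipleTesting:
    def test_family_wise_worked_example(self):
        # 1,320 pathways: threshold 0.05/1320 = 0.000038 (2 s.f.)
        n_sets = 1320
        threshold = 0.05 / n_sets
        assert float(f"{threshold:.2g}") == 3.8e-05
        results = [
            pcgsa.GeneSetResult("hit", 10, "competitive", 1, 1, 1, 0.000026),
            pcgsa.GeneSetResult("near", 10, "competitive", 1, 1, 1, 0.000094),
        ]
        multiple_testing_adjust(results, n_tests=n_sets)
        assert results[0].p_adjusted == pytest.approx(0.0343, abs=2e-4)
        assert results[0].significant
        assert not results[1].significant

    def test_p_one_stays_one(self):
        res = [pcgsa.GeneSetResult("s", 1, "competitive", 0, 1, 0, 1.0)]
        multiple_testing_adjust(res, n_tests=50)
        assert res[0].p_adjusted == 1.0

    def test_single_test_unchanged(self):
        res = [pcgsa.GeneSetResult("s", 1, "competitive", 0, 1, 0, 0.031)]
        multiple_testing_adjust(res)
        assert res[0].p_adjusted == 0.031

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            multiple_testing_adjust([], method="holm")
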