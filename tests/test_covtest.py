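import numpy as np
import pytest
import scipy.sparse as sp

from sparkx import (
    adjust_pvalues,
    build_context,
    cauchy_combine,
    gene_statistic,
    mixture_coefficients,
    sparkx_test,
    standardize,
    standardize_coordinates,
)
from sparkx.covtest import _batch_statistics


def dense_reference(y, S, X):
    """Brute-force T, lambda_E and lambda_Sigma from the explicit n x n
    covariance matrices; the oracle the fast path must reproduce."""
    n = y.size
    H = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    E = np.outer(y, y) / (y @ y)
    Sig = S @ np.linalg.solve(S.T @ S, S.T)
    Ec, Sc = H @ E @ H, H @ Sig @ H
    T = np.trace(Ec @ Sc) / n
    lam_e = np.linalg.eigvalsh(Ec).max()
    lam_s = np.sort(np.linalg.eigvalsh(Sc))[::-1][: S.shape[1]]
    return T, lam_e, lam_s


class TestProjectionContext:
    def test_identity_kernel_intercept_only_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        S = standardize_coordinates(rng.normal(size=(60, 2)))
        ctx = build_context(S, np.ones((60, 1)))
        np.testing.assert_allclose(ctx.lambda_Sigma, [1.0, 1.0], atol=1e-10)

    def test_coordinates_as_covariates_zero_eigenvalues(self):
        rng = np.random.default_rng(1)
        S = standardize_coordinates(rng.normal(size=(60, 2)))
        X = np.column_stack([np.ones(60), S])
        ctx = build_context(S, X)
        np.testing.assert_allclose(ctx.lambda_Sigma, 0.0, atol=1e-10)

    def test_eigenvalues_match_dense_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 50
            S = np.exp(-rng.normal(size=(n, 2)) ** 2)  # uncentered, kernel-like
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            ctx = build_context(S, X)
            y = rng.normal(size=n)
            _, _, lam_s = dense_reference(standardize(y), S, X)
            np.testing.assert_allclose(ctx.lambda_Sigma, lam_s, atol=1e-8)


class TestGeneStatistic:
    def test_perfect_projection(self):
        # y equal to the (centered, standardized) single coordinate: T = 1/n
        rng = np.random.default_rng(3)
        n = 40
        s = standardize(rng.normal(size=n))
        ctx = build_context(s[:, None], np.ones((n, 1)))
        T, lam_e = gene_statistic(s, ctx)
        assert T == pytest.approx(1.0 / n, abs=1e-12)
        assert lam_e == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vector_gives_zero(self):
        n = 40
        rng = np.random.default_rng(4)
        S = standardize_coordinates(rng.normal(size=(n, 2)))
        ctx = build_context(S, np.ones((n, 1)))
        y = rng.normal(size=n)
        # project out the span of {1, S}
        B = np.column_stack([np.ones(n), S])
        y = y - B @ np.linalg.lstsq(B, y, rcond=None)[0]
        y = standardize(y)
        T, _ = gene_statistic(y, ctx)
        assert T == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_oracle_on_sparse_counts(self):
        rng = np.random.default_rng(5)
        n = 100
        S = np.exp(-standardize_coordinates(rng.normal(size=(n, 2))) ** 2)
        X = np.column_stack([np.ones(n), (rng.uniform(size=n) > 0.5).astype(float)])
        ctx = build_context(S, X)
        for _ in range(5):
            raw = rng.poisson(0.2, size=n)
            if raw.std() == 0:
                continue
            y = standardize(raw)
            T, lam_e = gene_statistic(y, ctx)
            T_ref, lam_e_ref, _ = dense_reference(y, S, X)
            assert T == pytest.approx(T_ref, abs=1e-10)
            assert lam_e == pytest.approx(lam_e_ref, abs=1e-10)

    def test_batch_path_equals_per_gene_path(self):
        rng = np.random.default_rng(6)
        n, g = 150, 30
        counts = rng.negative_binomial(2, 0.7, size=(g, n))
        S = standardize_coordinates(rng.normal(size=(n, 2)))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        ctx = build_context(S, X)
        T_b, lam_b, degen = _batch_statistics(sp.csr_matrix(counts), ctx)
        for i in range(g):
            if degen[i]:
                continue
            T_i, lam_i = gene_statistic(standardize(counts[i]), ctx)
            assert T_b[i] == pytest.approx(T_i, rel=1e-10)
            assert lam_b[i] == pytest.approx(lam_i, rel=1e-10)


class TestMixtureCoefficients:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            mixture_coefficients(1.0, np.array([1.0, 1.0]), 10), [0.01, 0.01]
        )

    def test_zero_eigenvalue_removed(self):
        assert mixture_coefficients(1.0, np.array([1.0, 0.0]), 10).size == 1

    def test_conservation(self):
        rng = np.random.default_rng(7)
        lam = rng.uniform(0, 1, size=3)
        c = mixture_coefficients(0.9, lam, 50)
        assert c.sum() == pytest.approx(0.9 * lam.sum() / 2500, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mixture_coefficients(-0.5, np.array([1.0]), 10)


class TestCauchyCombine:
    def test_single_pvalue_identity(self):
        assert cauchy_combine([0.03]) == pytest.approx(0.03, abs=1e-12)

    @pytest.mark.parametrize("p0", [0.001, 0.2, 0.5, 0.93])
    def test_equal_pvalues_fixed_point(self, p0):
        assert cauchy_combine([p0] * 7) == pytest.approx(p0, abs=1e-10)

    def test_two_value_closed_form(self):
        # (1/2)[tan(0.49 pi) + tan(0)] back through arctan
        expect = 0.5 - np.arctan(np.tan(0.49 * np.pi) / 2) / np.pi
        assert expect == pytest.approx(0.019982, abs=1e-5)
        assert cauchy_combine([0.01, 0.5]) == pytest.approx(expect, abs=1e-12)

    def test_tiny_pvalues_do_not_overflow(self):
        out = cauchy_combine([1e-280, 0.4, 0.9])
        assert 0 < out < 1e-270

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cauchy_combine([])
        with pytest.raises(ValueError):
            cauchy_combine([0.0, 0.5])


class TestAdjustPvalues:
    def test_bh_closed_form(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03]
        )

    def test_single_unchanged_under_bh(self):
        assert adjust_pvalues([0.2], "BH")[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("method", ["BH", "BY"])
    def test_against_step_up_oracle(self, method):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        m = p.size
        cm = 1.0 if method == "BH" else float(np.sum(1.0 / np.arange(1, m + 1)))
        # exhaustive step-up definition
        order = np.argsort(p)
        expect = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * cm * m / rank)
            expect[order[rank - 1]] = running
        got = adjust_pvalues(p, method)
        np.testing.assert_allclose(got, expect, atol=1e-12)
        assert np.all(got >= p - 1e-12)


class TestSparkxTest:
    def test_constant_genes_reported_degenerate(self, tiny_coords):
        counts = sp.csr_matrix(np.ones((3, 5), dtype=int))
        res = sparkx_test(counts, tiny_coords)
        assert all(r.status == "degenerate_skipped" for r in res)
        assert all(np.isnan(r.combined_p) for r in res)

    def test_joint_permutation_invariance(self, moderate_null_dataset):
        ds = moderate_null_dataset
        sub = ds.counts.values[:15]
        rng = np.random.default_rng(9)
        perm = rng.permutation(ds.coords.n)
        p_ref = [r.combined_p for r in sparkx_test(sub, ds.coords.positions)]
        p_perm = [
            r.combined_p
            for r in sparkx_test(sub[:, perm], ds.coords.positions[perm])
        ]
        np.testing.assert_allclose(p_perm, p_ref, atol=1e-10)

    def test_coordinate_scale_invariance(self, moderate_null_dataset):
        ds = moderate_null_dataset
        sub = ds.counts.values[:15]
        p_ref = [r.combined_p for r in sparkx_test(sub, ds.coords.positions)]
        p_scaled = [
            r.combined_p for r in sparkx_test(sub, ds.coords.positions * 137.0)
        ]
        np.testing.assert_allclose(p_scaled, p_ref, atol=1e-10)

    def test_single_kernel_option(self, moderate_null_dataset):
        ds = moderate_null_dataset
        sub = ds.counts.values[:5]
        res = sparkx_test(sub, ds.coords.positions, option="single:gaussian_2")
        assert all(len(r.per_kernel) == 1 for r in res)
        assert res[0].per_kernel[0].label == "gaussian_2"
        # single-kernel combined p equals that kernel's p
        for r in res:
            assert r.combined_p == pytest.approx(r.per_kernel[0].p, abs=1e-12)

    def test_eleven_pvalues_per_gene(self, moderate_null_dataset):
        ds = moderate_null_dataset
        res = sparkx_test(ds.counts.values[:3], ds.coords.positions)
        assert all(len(r.per_kernel) == 11 for r in res)
        for r in res:
            assert 0 < r.combined_p <= 1
            assert r.adjusted_p >= r.combined_p - 1e-12

    def test_covariate_absorbs_its_own_signal(self):
        # a gene whose spatial pattern is entirely a binary covariate's effect
        import sparkx

        n = 1500
        coords = sparkx.simulate_locations(n, 11)
        mask = sparkx.mark_hotspot(coords, 0.2)
        mu = sparkx.apply_fold_change(0.5, mask, 3.0, "up")
        counts = sp.csr_matrix(sparkx.nb_counts(mu, 0.2, (1, n), 12))
        p_raw = sparkx_test(counts, coords)[0].combined_p
        X = np.column_stack([np.ones(n), mask.astype(float)])
        p_adj = sparkx_test(counts, coords, X=X)[0].combined_p
        assert p_raw < 1e-8
        assert p_adj > 1e-3

    def test_expression_scaling_leaves_p_invariant(self, moderate_null_dataset):
        # population-sd vs sample-sd standardization only rescales y; the
        # statistic is scale-free in y, so p-values cannot move
        ds = moderate_null_dataset
        sub = ds.counts.values[:10]
        p_ref = [r.combined_p for r in sparkx_test(sub, ds.coords.positions)]
        p_scaled = [r.combined_p for r in sparkx_test(sub * 3, ds.coords.positions)]
        np.testing.assert_allclose(p_scaled, p_ref, atol=1e-10)
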