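"""Mixed-model adjustment: fits, residual notions, whitening, fixed-only path."""

import numpy as np
import pandas as pd
import pytest

from rmapcoa import (
    SampleDesign,
    adjust_kernel_fixed_only,
    adjust_kernel_fixed_only_via_pcs,
    adjust_pcs_repeated,
    aitchison_distance,
    conditional_residuals,
    fit_pc_lmm,
    gower_center,
    kernel_pcs,
    marginal_covariance,
    marginal_residuals,
    retain_pcs,
    standardize_residuals,
)
from rmapcoa.mixed_adjust import PcLmmFit


def _design(n=10, m=3, seed=5, **kw):
    rng = np.random.default_rng(seed)
    md = pd.DataFrame(
        {
            "subject": np.repeat([f"s{i}" for i in range(n)], m),
            "time": np.tile(np.arange(m), n),
            "grp": np.repeat(rng.integers(0, 2, n).astype(str), m),
        },
        index=[f"obs{i}" for i in range(n * m)],
    )
    kw.setdefault("fixed_formula", "grp")
    return SampleDesign(md, subject_col="subject", time_col="time", **kw)


class TestSampleDesign:
    def test_missing_subject_column(self):
        md = pd.DataFrame({"x": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="subject"):
            SampleDesign(md, subject_col="subject")

    def test_rank_deficient_design_names_columns(self):
        md = pd.DataFrame(
            {"subject": ["a", "a", "b", "b"], "x": [1.0, 1.0, 2.0, 2.0],
             "y": [2.0, 2.0, 4.0, 4.0]},
            index=list("pqrs"),
        )
        with pytest.raises(ValueError, match="rank deficient"):
            SampleDesign(md, subject_col="subject", fixed_formula="x + y")

    def test_non_contiguous_subjects_rejected(self):
        md = pd.DataFrame({"subject": ["a", "b", "a"]}, index=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="contiguous"):
            SampleDesign(md, subject_col="subject")

    def test_canonical_order_sorts_by_subject_then_time(self):
        md = pd.DataFrame(
            {"subject": ["b", "a", "b", "a"], "time": [1, 1, 0, 0]},
            index=["w", "x", "y", "z"],
        )
        d = SampleDesign(
            md.sort_values("subject"), subject_col="subject", time_col="time"
        )
        ordered = d.reordered(d.canonical_order())
        assert list(ordered.metadata["subject"]) == ["a", "a", "b", "b"]
        assert list(ordered.metadata["time"]) == [0, 1, 0, 1]

    def test_categorical_time_enters_fixed_design(self):
        d = _design(fixed_formula="grp + time")
        assert sum("time" in c for c in d.exog_names) == 2  # m-1 dummy columns

    def test_random_slope_z_block(self):
        d = _design(random_slope=True)
        z = d.z_block("s0")
        np.testing.assert_allclose(z, [[1, 0], [1, 1], [1, 2]])


class TestFitPcLmm:
    def test_noiseless_recovery(self):
        d = _design(n=20, m=3)
        beta = np.array([1.5, -2.0])
        pc = d.exog @ beta
        fit = fit_pc_lmm(pc, d)
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-4)
        assert fit.resid_var_hat < 1e-6

    def test_reml_matches_reference_estimates(self):
        """Cross-check variance components against an independent profile
        likelihood maximisation on a balanced random-intercept dataset."""
        rng = np.random.default_rng(3)
        n, m = 60, 4
        md = pd.DataFrame(
            {"subject": np.repeat([f"s{i}" for i in range(n)], m),
             "time": np.tile(np.arange(m), n)},
            index=[f"o{i}" for i in range(n * m)],
        )
        d = SampleDesign(md, subject_col="subject", time_col="time",
                         fixed_formula=None)
        y = 1.0 + np.repeat(rng.normal(0, 1.2, n), m) + rng.normal(0, 0.8, n * m)
        fit = fit_pc_lmm(y, d)

        # independent oracle: closed-form REML for balanced one-way layout
        ybar_i = y.reshape(n, m).mean(axis=1)
        ybar = y.mean()
        ss_within = ((y.reshape(n, m) - ybar_i[:, None]) ** 2).sum()
        ss_between = m * ((ybar_i - ybar) ** 2).sum()
        sigma2 = ss_within / (n * (m - 1))
        tau2 = max((ss_between / (n - 1) - sigma2) / m, 0.0)
        assert fit.resid_var_hat == pytest.approx(sigma2, rel=1e-3)
        assert fit.random_cov_hat[0, 0] == pytest.approx(tau2, rel=1e-2)

    def test_single_observation_per_subject_degenerates(self):
        md = pd.DataFrame(
            {"subject": ["a", "b", "c", "d", "e"], "x": [0.0, 1.0, 2.0, 3.0, 4.0]},
            index=list("pqrst"),
        )
        d = SampleDesign(md, subject_col="subject", fixed_formula="x")
        with pytest.warns(RuntimeWarning, match="not separately identified"):
            fit = fit_pc_lmm(np.arange(5.0), d)
        assert fit.method == "OLS-fallback"
        assert not fit.identified
        np.testing.assert_allclose(fit.random_cov_hat, 0.0)


class TestResiduals:
    def test_marginal_matrix_product_oracle(self, rng):
        d = _design(n=15, m=3)
        pc = rng.normal(size=d.n_samples)
        fit = fit_pc_lmm(pc, d)
        np.testing.assert_allclose(
            marginal_residuals(fit, pc, d), pc - d.exog @ fit.beta_hat
        )

    def test_zero_beta_gives_pc_back(self, rng):
        d = _design()
        pc = rng.normal(size=d.n_samples)
        fit = PcLmmFit(0, np.zeros(d.exog.shape[1]), np.zeros((1, 1)), 1.0,
                       {s: np.zeros(1) for s in d.subjects}, True, "REML")
        np.testing.assert_allclose(marginal_residuals(fit, pc, d), pc)

    def test_conditional_removes_subject_offsets(self):
        """Noiseless per-subject offsets: marginal residuals keep the offsets,
        conditional residuals shrink them nearly away."""
        d = _design(n=30, m=4, fixed_formula=None)
        rng = np.random.default_rng(0)
        offsets = rng.normal(0, 3.0, 30)
        pc = np.repeat(offsets, 4) + rng.normal(0, 0.05, 120)
        fit = fit_pc_lmm(pc, d)
        marg = marginal_residuals(fit, pc, d)
        cond = conditional_residuals(fit, pc, d)
        assert np.std(cond) < 0.15 * np.std(marg)
        np.testing.assert_allclose(
            cond,
            pc - d.exog @ fit.beta_hat
            - np.concatenate([d.z_block(s) @ fit.blup[s] for s in d.subjects]),
        )

    def test_fallback_conditional_equals_marginal_with_warning(self, rng):
        d = _design()
        pc = rng.normal(size=d.n_samples)
        fit = PcLmmFit(0, np.zeros(d.exog.shape[1]), np.zeros((1, 1)), 1.0,
                       {s: np.zeros(1) for s in d.subjects}, False, "OLS-fallback")
        with pytest.warns(RuntimeWarning, match="marginal"):
            cond = conditional_residuals(fit, pc, d)
        np.testing.assert_allclose(cond, marginal_residuals(fit, pc, d))


class TestMarginalCovariance:
    def _fit(self, d, g, s2):
        g = np.atleast_2d(g)
        return PcLmmFit(0, np.zeros(d.exog.shape[1]), g, s2,
                        {s: np.zeros(g.shape[0]) for s in d.subjects}, True, "REML")

    def test_identity_when_no_random_variance(self):
        d = _design()
        v = marginal_covariance(self._fit(d, 0.0, 1.0), d, "s0")
        np.testing.assert_allclose(v, np.eye(3))

    def test_compound_symmetry_closed_form(self):
        d = _design()
        tau2, s2 = 2.5, 0.7
        v = marginal_covariance(self._fit(d, tau2, s2), d, "s1")
        np.testing.assert_allclose(v, s2 * np.eye(3) + tau2 * np.ones((3, 3)))

    def test_random_slope_brute_force(self):
        d = _design(random_slope=True)
        g = np.array([[1.0, 0.3], [0.3, 0.5]])
        fit = self._fit(d, g, 0.9)
        z = d.z_block("s2")
        np.testing.assert_allclose(
            marginal_covariance(fit, d, "s2"), z @ g @ z.T + 0.9 * np.eye(3)
        )


class TestStandardizeResiduals:
    def test_identity_whitening(self, rng):
        d = _design(n=4, m=3)
        e = rng.normal(size=d.n_samples)
        vhats = {s: np.eye(3) for s in d.subjects}
        np.testing.assert_allclose(standardize_residuals(e, vhats, d), e)

    def test_scalar_scaling(self):
        md = pd.DataFrame({"subject": ["a", "a"]}, index=["x", "y"])
        d = SampleDesign(md, subject_col="subject")
        out = standardize_residuals(np.array([2.0, 2.0]), {"a": 4.0 * np.eye(2)}, d)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_whitening_inverts_cholesky(self, rng):
        """L e* == e for a full compound-symmetry block."""
        d = _design(n=3, m=3)
        v = 0.6 * np.eye(3) + 1.4 * np.ones((3, 3))
        e = rng.normal(size=9)
        out = standardize_residuals(e, {s: v for s in d.subjects}, d)
        L = np.linalg.cholesky(v)
        for s, sl in d.block_slices.items():
            np.testing.assert_allclose(L @ out[sl], e[sl], atol=1e-10)

    def test_monte_carlo_whitening(self, rng):
        """Empirical covariance of whitened compound-symmetry draws ≈ identity."""
        m, reps = 4, 4000
        v = np.eye(m) + 1.5 * np.ones((m, m))
        L = np.linalg.cholesky(v)
        draws = rng.normal(size=(reps, m)) @ L.T
        white = np.linalg.solve(L, draws.T).T
        c = white.T @ white / reps
        assert np.linalg.norm(c - np.eye(m)) / np.linalg.norm(np.eye(m)) < 0.05

    def test_singular_block_gets_jitter(self):
        md = pd.DataFrame({"subject": ["a", "a"]}, index=["x", "y"])
        d = SampleDesign(md, subject_col="subject")
        v = np.ones((2, 2))  # rank 1
        with pytest.warns(RuntimeWarning, match="jitter"):
            out = standardize_residuals(np.array([1.0, 1.0]), {"a": v}, d)
        assert np.isfinite(out).all()


class TestAdjustPcsRepeated:
    def test_intercept_only_marginal_centers_pcs(self, rng):
        d = _design(n=8, m=3, fixed_formula=None)
        clr = rng.normal(size=(d.n_samples, 10))
        dec = retain_pcs(kernel_pcs(gower_center(aitchison_distance(clr))), 0.9)
        resid = adjust_pcs_repeated(dec, d, "marginal")
        # kernel PCs of a centered K are mean-zero, so centering is a no-op
        np.testing.assert_allclose(
            resid.values, dec.retained_pcs - dec.retained_pcs.mean(axis=0), atol=1e-8
        )

    def test_single_pc_edge_case(self, rng):
        d = _design(n=8, m=3, fixed_formula=None)
        clr = rng.normal(size=(d.n_samples, 10))
        dec = retain_pcs(kernel_pcs(gower_center(aitchison_distance(clr))), 0.9)
        from dataclasses import replace

        dec1 = replace(dec, n_retained=1)
        resid = adjust_pcs_repeated(dec1, d, "standardized")
        assert resid.values.shape == (d.n_samples, 1)
        assert len(resid.diagnostics) == 1

    def test_diagnostics_recorded_per_pc(self, rng):
        d = _design(n=10, m=3)
        clr = rng.normal(size=(d.n_samples, 12))
        dec = retain_pcs(kernel_pcs(gower_center(aitchison_distance(clr))), 0.8)
        resid = adjust_pcs_repeated(dec, d, "standardized")
        assert list(resid.diagnostics.columns[:3]) == ["method", "converged", "resid_var"]
        assert len(resid.diagnostics) == dec.n_retained


class TestFixedOnlyAdjustment:
    def test_intercept_on_centered_kernel_is_noop(self, rng):
        clr = rng.normal(size=(12, 8))
        k = gower_center(aitchison_distance(clr))
        np.testing.assert_allclose(
            adjust_kernel_fixed_only(k, np.ones((12, 1))), k, atol=1e-10
        )

    def test_full_projection_annihilates(self, rng):
        x = rng.normal(size=(10, 2))
        phi = x @ rng.normal(size=(2, 2))
        k = phi @ phi.T
        np.testing.assert_allclose(
            adjust_kernel_fixed_only(k, x), 0.0, atol=1e-10
        )

    def test_dual_formula_agreement(self, rng):
        clr = rng.normal(size=(15, 9))
        k = gower_center(aitchison_distance(clr))
        dec = kernel_pcs(k)
        x = np.column_stack([np.ones(15), rng.normal(size=(15, 2))])
        k1 = adjust_kernel_fixed_only(k, x)
        k2 = adjust_kernel_fixed_only_via_pcs(dec, x)
        np.testing.assert_allclose(k1, k2, atol=1e-10)

    def test_residual_columns_orthogonal_to_covariates(self, rng):
        clr = rng.normal(size=(15, 9))
        dec = kernel_pcs(gower_center(aitchison_distance(clr)))
        x = np.column_stack([np.ones(15), rng.normal(size=(15, 2))])
        p = np.eye(15) - x @ np.linalg.pinv(x)
        e = p @ dec.pcs
        for j in range(x.shape[1]):
            for r in range(e.shape[1]):
                num = abs(x[:, j] @ e[:, r])
                assert num < 1e-8 * np.linalg.norm(x[:, j]) * max(np.linalg.norm(e[:, r]), 1e-30)

    def test_rank_deficiency_rejected(self, rng):
        k = np.eye(6)
        x = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            adjust_kernel_fixed_only(k, x)
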