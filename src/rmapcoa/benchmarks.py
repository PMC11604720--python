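"""Self-contained calibration and benchmark computations.

These routines quantify, on simulated data with known truth, the properties
the method claims: exact agreement of the two cross-sectional adjustment
formulas, classical-MDS exactness of the Aitchison pipeline, whitening of
standardized residual blocks, recovery of variance components, and the
separation gains on the generative scenarios. They are used by the test
suite and the reproduction script alike.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import pdist, squareform

from .evaluate import group_silhouette, stratified_silhouette
from .kernels import (
    AbundanceTable,
    aitchison_distance,
    clr_transform,
    gower_center,
    kernel_pcs,
    retain_pcs,
)
from .mixed_adjust import (
    SampleDesign,
    adjust_kernel_fixed_only,
    adjust_kernel_fixed_only_via_pcs,
    adjust_pcs_repeated,
    fit_pc_lmm,
)
from .model import RepeatedMeasuresAPCoA, WorkflowConfig, run_fixed_only_apcoa
from .ordination import pcoa, reconstruct_kernel
from .simulate import ScenarioConfig, scenario_clustered, scenario_time_invariant

import pandas as pd

__all__ = [
    "fixed_only_equivalence",
    "mds_exactness",
    "whitening_calibration",
    "lmm_parameter_recovery",
    "scenario1_separation",
    "scenario3_separation",
    "null_adjustment_error",
]


def _random_cross_sectional(n: int, p: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random CLR-like data and a fixed design (intercept + binary + numeric)."""
    z = rng.normal(size=(n, p))
    z -= z.mean(axis=1, keepdims=True)
    x = np.column_stack(
        [np.ones(n), rng.integers(0, 2, size=n).astype(float), rng.normal(size=n)]
    )
    return z, x


def fixed_only_equivalence(seed: int = 0, n: int = 30, p: int = 20) -> dict:
    """Agreement of the three routes to the cross-sectional adjusted kernel.

    On random data: (a) the projection formula (I−P_X) K (I−P_X); (b) the
    per-PC OLS residual construction E E'; (c) the repeated-measures pipeline
    run with one observation per subject, marginal residuals and full PC
    retention. Returns the maximum absolute elementwise discrepancies.
    """
    rng = np.random.default_rng(seed)
    z, x = _random_cross_sectional(n, p, rng)
    dist = aitchison_distance(z)
    k = gower_center(dist)
    dec = kernel_pcs(k)

    k_proj = adjust_kernel_fixed_only(k, x)
    k_resid = adjust_kernel_fixed_only_via_pcs(dec, x)

    md = pd.DataFrame(
        {"subject": [f"s{i}" for i in range(n)], "x1": x[:, 1], "x2": x[:, 2]},
        index=[f"obs{i}" for i in range(n)],
    )
    design = SampleDesign(md, subject_col="subject", fixed_formula="x1 + x2")
    resid = adjust_pcs_repeated(retain_pcs(dec, 1.0), design, "marginal")
    k_pipeline = reconstruct_kernel(resid)
    return {
        "proj_vs_resid": float(np.abs(k_proj - k_resid).max()),
        "proj_vs_pipeline": float(np.abs(k_proj - k_pipeline).max()),
        "n": n,
    }


def mds_exactness(seed: int = 0, n: int = 40, p: int = 30) -> dict:
    """Classical-MDS exactness of the Aitchison pipeline.

    Euclidean distances among the full-rank kernel-PC embedding must
    reproduce the input Aitchison distances; kernel rows must sum to zero.
    """
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 200, size=(n, p)).astype(float)
    table = AbundanceTable(counts)
    clr = clr_transform(table, 0.5)
    dist = aitchison_distance(clr)
    k = gower_center(dist)
    dec = kernel_pcs(k)
    d_embed = squareform(pdist(dec.pcs))
    return {
        "distance_max_error": float(np.abs(d_embed - dist.values).max()),
        "kernel_row_sum_max": float(np.abs(k.sum(axis=1)).max()),
        "n": n,
    }


def whitening_calibration(
    seed: int = 0,
    n_subjects: int = 50,
    m: int = 4,
    n_reps: int = 10_000,
    tau2: float = 1.0,
    sigma2: float = 1.0,
) -> dict:
    """Whitening contract: var(e*) ≈ I on data simulated from a fitted LMM.

    One random-intercept dataset is fitted by REML; replicate datasets are
    then drawn from the fitted variance components, fixed effects re-estimated
    per replicate by GLS at the fitted V̂ (the REML β̂ given those components),
    marginal residual blocks whitened with the fitted Cholesky factor, and the
    pooled empirical block covariance compared to the identity:
    ‖Ĉ − I‖_F / ‖I‖_F.
    """
    rng = np.random.default_rng(seed)
    n, M = n_subjects, n_subjects * m
    t = np.tile(np.arange(m, dtype=float), n)
    x = np.column_stack([np.ones(M), t, rng.normal(size=M)])
    beta = np.array([1.0, 0.5, -0.3])
    b = rng.normal(0, np.sqrt(tau2), size=n)
    y = x @ beta + np.repeat(b, m) + rng.normal(0, np.sqrt(sigma2), size=M)

    md = pd.DataFrame(
        {
            "subject": np.repeat([f"s{i}" for i in range(n)], m),
            "time": t,
            "cov": x[:, 2],
        },
        index=[f"obs{i}" for i in range(M)],
    )
    design = SampleDesign(md, subject_col="subject", time_col="time",
                          fixed_formula="time + cov", time_as_categorical=False)
    fit = fit_pc_lmm(y, design)

    tau2_hat = fit.random_cov_hat[0, 0]
    sig2_hat = fit.resid_var_hat
    v_hat = tau2_hat * np.ones((m, m)) + sig2_hat * np.eye(m)
    L = cholesky(v_hat, lower=True)

    # GLS machinery at the fitted components (identical V̂ for every block)
    w = np.linalg.inv(v_hat)
    xb = x.reshape(n, m, -1)
    xtwx = np.einsum("nmi,mk,nkj->ij", xb, w, xb)
    a_inv = np.linalg.inv(xtwx)

    mu = x @ fit.beta_hat
    b_rep = rng.normal(0, np.sqrt(max(tau2_hat, 0.0)), size=(n_reps, n))
    eps = rng.normal(0, np.sqrt(sig2_hat), size=(n_reps, n, m))
    y_rep = mu.reshape(n, m) + b_rep[:, :, None] + eps  # (reps, n, m)

    xtwy = np.einsum("nmi,mk,rnk->ri", xb, w, y_rep)
    beta_rep = xtwy @ a_inv.T  # (reps, q)
    resid = y_rep - np.einsum("nmi,ri->rnm", xb, beta_rep)
    e_star = solve_triangular(L, resid.reshape(-1, m).T, lower=True).T
    c = e_star.T @ e_star / e_star.shape[0]
    rel = float(np.linalg.norm(c - np.eye(m)) / np.linalg.norm(np.eye(m)))
    return {
        "frobenius_rel_error": rel,
        "tau2_hat": float(tau2_hat),
        "sigma2_hat": float(sig2_hat),
        "n": n_reps,
    }


def lmm_parameter_recovery(
    seed: int = 0,
    n_subjects: int = 100,
    m: int = 4,
    n_reps: int = 40,
    tau2: float = 1.0,
    sigma2: float = 1.0,
) -> dict:
    """Monte-Carlo recovery of the random-intercept and residual variances.

    ``n_reps`` independent datasets are generated from a random-intercept
    model and fitted by REML; returns the mean estimates, their Monte-Carlo
    standard errors, and the true values.
    """
    rng = np.random.default_rng(seed)
    n, M = n_subjects, n_subjects * m
    t = np.tile(np.arange(m, dtype=float), n)
    md = pd.DataFrame(
        {"subject": np.repeat([f"s{i}" for i in range(n)], m), "time": t},
        index=[f"obs{i}" for i in range(M)],
    )
    design = SampleDesign(md, subject_col="subject", time_col="time",
                          fixed_formula="time", time_as_categorical=False)
    x = design.exog
    beta = np.array([2.0, -0.5])
    tau2_hats, sig2_hats = [], []
    for _ in range(n_reps):
        b = rng.normal(0, np.sqrt(tau2), size=n)
        y = x @ beta + np.repeat(b, m) + rng.normal(0, np.sqrt(sigma2), size=M)
        fit = fit_pc_lmm(y, design)
        tau2_hats.append(fit.random_cov_hat[0, 0])
        sig2_hats.append(fit.resid_var_hat)
    tau2_hats, sig2_hats = np.array(tau2_hats), np.array(sig2_hats)
    return {
        "tau2_mean": float(tau2_hats.mean()),
        "tau2_mc_se": float(tau2_hats.std(ddof=1) / np.sqrt(n_reps)),
        "tau2_true": tau2,
        "sigma2_mean": float(sig2_hats.mean()),
        "sigma2_mc_se": float(sig2_hats.std(ddof=1) / np.sqrt(n_reps)),
        "sigma2_true": sigma2,
        "n": n_reps,
    }


def scenario1_separation(seed: int = 0, config: ScenarioConfig = None) -> dict:
    """Treatment/sex separation under the three adjustment strategies.

    Runs the time-invariant-nuisance scenario at its default conditions and
    measures, on PC1–PC2 at the post-baseline time points, the silhouette of
    the treatment arms under (a) no adjustment, (b) fixed-effects-only sex
    adjustment, and (c) the repeated-measures mixed-model adjustment — plus
    the sex silhouette after (c).
    """
    config = config or ScenarioConfig(seed=seed)
    study = scenario_time_invariant(config)
    model = RepeatedMeasuresAPCoA(
        study.table,
        study.design.metadata,
        fixed_formula="sex + time + sex:time",
        random_formula="1|subject",
    )
    res = model.fit()
    md = res.design.metadata
    post = sorted(md["time"].unique())[1:]

    def sil(coords, var):
        return stratified_silhouette(coords, md[var], md["time"], include=post)

    adj = res.ordination.coordinates((1, 2))
    unadj = res.unadjusted.pcs[:, :2]
    fixed_design = SampleDesign(md, subject_col="subject", time_col="time",
                                fixed_formula="sex")
    fixed = run_fixed_only_apcoa(model.table, fixed_design)[None]
    fixed_coords = fixed.coordinates((1, 2))
    return {
        "treatment_silhouette_adjusted": sil(adj, "arm"),
        "treatment_silhouette_unadjusted": sil(unadj, "arm"),
        "treatment_silhouette_fixed_only": sil(fixed_coords, "arm"),
        "sex_silhouette_adjusted": sil(adj, "sex"),
        "sex_silhouette_unadjusted": sil(unadj, "sex"),
        "n_retained": int(res.unadjusted.n_retained),
        "prop_explained_at_retention": float(res.unadjusted.prop_explained),
        "n": study.table.n_samples,
    }


def scenario3_separation(seed: int = 0, config: ScenarioConfig = None) -> dict:
    """Family-cluster vs treatment-arm separation in the clustered scenario."""
    config = config or ScenarioConfig(n_subjects=30, seed=seed)
    study = scenario_clustered(config)
    model = RepeatedMeasuresAPCoA(
        study.table,
        study.design.metadata,
        fixed_formula=None,
        random_formula="1|family",
        time_col=None,
    )
    res = model.fit()
    md = res.design.metadata
    adj = res.ordination.coordinates((1, 2))
    unadj = res.unadjusted.pcs[:, :2]
    return {
        "family_silhouette_adjusted": group_silhouette(adj, md["family"]),
        "family_silhouette_unadjusted": group_silhouette(unadj, md["family"]),
        "treatment_silhouette_adjusted": group_silhouette(adj, md["arm"]),
        "treatment_silhouette_unadjusted": group_silhouette(unadj, md["arm"]),
        "n_retained": int(res.unadjusted.n_retained),
        "prop_explained_at_retention": float(res.unadjusted.prop_explained),
        "n": study.table.n_samples,
    }


def null_adjustment_error(seed: int = 0, n: int = 25, p: int = 15) -> dict:
    """Round-trip identity: with no covariates, no random effects, marginal
    residuals and full retention, the adjusted coordinates equal the plain
    PCoA coordinates up to axis sign."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 150, size=(n, p)).astype(float)
    table = AbundanceTable(counts)
    md = pd.DataFrame(index=table.sample_ids)
    model = RepeatedMeasuresAPCoA(
        table,
        md,
        fixed_formula=None,
        random_formula=None,
        residual_type="marginal",
        retention_threshold=1.0,
        time_col=None,
    )
    res = model.fit()
    plain = pcoa(res.unadjusted.kernel)
    a, b = res.ordination.pcs_adj, plain.pcs_adj
    k = min(a.shape[1], b.shape[1])
    err = 0.0
    for j in range(k):
        err = max(err, min(np.abs(a[:, j] - b[:, j]).max(),
                           np.abs(a[:, j] + b[:, j]).max()))
    return {"max_coordinate_error": float(err), "n": n}
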