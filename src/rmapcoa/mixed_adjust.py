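"""Per-PC covariate adjustment with linear mixed models.

Each retained kernel PC Φ^(r) is modelled as

    Φ_i^(r) = x_i β^(r) + z_i γ_i^(r) + ε_i^(r)

with fixed nuisance covariates x_i, a per-subject (or per-cluster) random
intercept — optionally a random slope on time — and iid error. Three notions
of residual are available:

* marginal:     e_i = Φ_i − x_i β̂           (population-level)
* conditional:  e_i = Φ_i − x_i β̂ − z_i γ̂_i (BLUPs subtracted)
* standardized: e*_i = L_i^{-1} e_i, where V̂_i = Z_i Ĝ Z_i' + σ̂² I = L_i L_i'
                is the estimated marginal covariance of subject i's block and
                L_i its lower Cholesky factor, so var(e*_i) ≈ I.

Standardized residuals are the recommended default: subtracting estimated
fixed effects leaves within-subject dependence in the marginal residuals that
whitening removes, which matters when the dependence itself is nuisance.

The cross-sectional, fixed-effects-only adjustment

    K_adj = (I − X(X'X)^{-1}X') K (I − X(X'X)^{-1}X')

is also provided: it equals E E' with E the per-PC OLS residuals, and serves
as the degenerate case (one observation per subject, no random effects) of
the repeated-measures pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import patsy
from scipy.linalg import cholesky, qr, solve_triangular
import statsmodels.api as sm

from .kernels import KernelDecomposition

__all__ = [
    "SampleDesign",
    "PcLmmFit",
    "ResidualMatrix",
    "fit_pc_lmm",
    "marginal_residuals",
    "conditional_residuals",
    "marginal_covariance",
    "standardize_residuals",
    "adjust_pcs_repeated",
    "adjust_kernel_fixed_only",
    "adjust_kernel_fixed_only_via_pcs",
]

RESIDUAL_TYPES = ("marginal", "conditional", "standardized")


def _check_full_rank(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        _, r, piv = qr(x, pivoting=True, mode="economic")
        keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
        dropped = [names[piv[i]] for i in range(len(keep)) if not keep[i]]
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {dropped}"
        )


class SampleDesign:
    """Per-sample metadata: subject/cluster grouping, time, fixed covariates.

    Parameters
    ----------
    metadata : DataFrame
        One row per sample, indexed by sample ID.
    subject_col : str or None
        Column giving the subject/cluster label (random-effect grouping).
        ``None`` means every sample is its own subject (no random effects
        are identifiable; fits fall back to OLS).
    time_col : str or None
        Column giving the within-subject measurement time/index.
    fixed_formula : str or None
        Patsy right-hand-side formula for the fixed nuisance covariates,
        e.g. ``"sex + time + sex:time"``. ``None`` fits an intercept only.
    random_slope : bool
        Add a per-subject random slope on (numeric) time alongside the
        random intercept.
    time_as_categorical : bool
        Code the time column as a categorical factor in the fixed design
        (the default for discrete visit indices); numeric coding otherwise.
    """

    def __init__(
        self,
        metadata: pd.DataFrame,
        subject_col: Optional[str] = "subject",
        time_col: Optional[str] = None,
        fixed_formula: Optional[str] = None,
        random_slope: bool = False,
        time_as_categorical: bool = True,
    ):
        metadata = metadata.copy()
        if metadata.index.has_duplicates:
            raise ValueError("duplicate sample IDs in metadata index")
        for col in (subject_col, time_col):
            if col is not None and col not in metadata.columns:
                raise ValueError(f"metadata is missing required column '{col}'")
        if subject_col is not None and metadata[subject_col].isna().any():
            bad = list(metadata.index[metadata[subject_col].isna()])
            raise ValueError(f"samples without a subject ID: {bad[:5]}")
        if random_slope and time_col is None:
            raise ValueError("random_slope requires a time column")
        self.metadata = metadata
        self.subject_col = subject_col
        self.time_col = time_col
        self.fixed_formula = fixed_formula
        self.random_slope = random_slope
        self.time_as_categorical = time_as_categorical
        self._build()

    def _build(self) -> None:
        md = self.metadata
        env = md.copy()
        if (
            self.time_col is not None
            and self.time_as_categorical
            and self.time_col in env.columns
        ):
            env[self.time_col] = env[self.time_col].astype("category")
        if self.fixed_formula:
            dm = patsy.dmatrix(self.fixed_formula, env, return_type="dataframe")
            if len(dm) != len(md):
                missing = md.index.difference(dm.index)
                raise ValueError(
                    f"covariates missing for samples: {list(missing)[:5]}"
                )
        else:
            dm = pd.DataFrame({"Intercept": np.ones(len(md))}, index=md.index)
        self.exog = dm.to_numpy(dtype=float)
        self.exog_names = list(dm.columns)
        _check_full_rank(self.exog, self.exog_names)
        if self.subject_col is not None:
            self.groups = md[self.subject_col].to_numpy()
        else:
            self.groups = np.asarray(md.index)
        # contiguous per-subject blocks in current sample order
        codes, uniques = pd.factorize(self.groups)
        self._group_codes = codes
        self.subjects = list(uniques)
        self.block_slices = {}
        seen = set()
        idx = 0
        while idx < len(codes):
            c = codes[idx]
            j = idx
            while j < len(codes) and codes[j] == c:
                j += 1
            subj = uniques[c]
            if subj in seen:
                raise ValueError(
                    f"samples of subject '{subj}' are not contiguous; "
                    "sort samples by subject (and time) first"
                )
            seen.add(subj)
            self.block_slices[subj] = slice(idx, j)
            idx = j
        if self.random_slope:
            t = pd.to_numeric(md[self.time_col]).to_numpy(dtype=float)
            self.exog_re = np.column_stack([np.ones(len(md)), t])
            self.exog_re_names = ["Intercept", self.time_col]
        else:
            self.exog_re = np.ones((len(md), 1))
            self.exog_re_names = ["Intercept"]

    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    @property
    def sample_ids(self) -> list:
        return list(self.metadata.index)

    @property
    def max_block_size(self) -> int:
        return max(s.stop - s.start for s in self.block_slices.values())

    def canonical_order(self) -> np.ndarray:
        """Stable sample ordering: by subject (first appearance), then time."""
        md = self.metadata
        keys = [pd.factorize(self.groups)[0]]
        if self.time_col is not None:
            keys.append(pd.factorize(md[self.time_col], sort=True)[0])
        order = np.lexsort(tuple(reversed(keys)))
        return order

    def reordered(self, order: np.ndarray) -> "SampleDesign":
        return SampleDesign(
            self.metadata.iloc[order],
            self.subject_col,
            self.time_col,
            self.fixed_formula,
            self.random_slope,
            self.time_as_categorical,
        )

    def z_block(self, subject) -> np.ndarray:
        """Random-effect design Z_i for one subject's block."""
        return self.exog_re[self.block_slices[subject]]


@dataclass
class PcLmmFit:
    """Mixed-model fit for one kernel PC."""

    pc_index: int
    beta_hat: np.ndarray
    random_cov_hat: np.ndarray  # Ĝ, q_re x q_re
    resid_var_hat: float  # σ̂²
    blup: dict  # subject -> γ̂_i vector
    converged: bool
    method: str  # "REML" | "ML" | "OLS-fallback"
    identified: bool = True


@dataclass
class ResidualMatrix:
    """M x ℓ matrix of per-PC LMM residuals of one residual type."""

    values: np.ndarray
    residual_type: str
    diagnostics: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.residual_type not in RESIDUAL_TYPES:
            raise ValueError(f"residual_type must be one of {RESIDUAL_TYPES}")


def _ols_fallback(pc: np.ndarray, design: SampleDesign, r: int, converged=False,
                  identified=True) -> PcLmmFit:
    x = design.exog
    beta, *_ = np.linalg.lstsq(x, pc, rcond=None)
    resid = pc - x @ beta
    dof = max(len(pc) - x.shape[1], 1)
    q = design.exog_re.shape[1]
    return PcLmmFit(
        pc_index=r,
        beta_hat=beta,
        random_cov_hat=np.zeros((q, q)),
        resid_var_hat=float(resid @ resid / dof),
        blup={s: np.zeros(q) for s in design.subjects},
        converged=converged,
        method="OLS-fallback",
        identified=identified,
    )


def fit_pc_lmm(pc: np.ndarray, design: SampleDesign) -> PcLmmFit:
    """Fit one kernel PC against the design: REML, retrying with ML, finally
    falling back to OLS (Ĝ = 0) if neither optimizer converges."""
    pc = np.asarray(pc, dtype=float).ravel()
    if len(pc) != design.n_samples:
        raise ValueError("PC length does not match the design")
    if design.n_samples <= design.exog.shape[1]:
        raise ValueError("more fixed-effect columns than samples")
    r = -1
    if design.max_block_size == 1:
        warnings.warn(
            "single observation per subject: random-intercept and residual "
            "variances are not separately identified; using OLS",
            RuntimeWarning,
            stacklevel=2,
        )
        return _ols_fallback(pc, design, r, identified=False)

    def _try(reml: bool):
        model = sm.MixedLM(
            pc, design.exog, groups=design._group_codes, exog_re=design.exog_re
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml)
        if not res.converged or not np.isfinite(res.params).all():
            return None
        return res

    res, method = None, None
    try:
        res, method = _try(True), "REML"
    except Exception:
        res = None
    if res is None:
        try:
            res, method = _try(False), "ML"
        except Exception:
            res = None
    if res is None:
        return _ols_fallback(pc, design, r)

    g = np.asarray(res.cov_re, dtype=float)
    g = 0.5 * (g + g.T)
    # PSD guard: boundary fits can leave tiny negative curvature
    w, v = np.linalg.eigh(g)
    if w.min(initial=0.0) < 0:
        g = (v * np.clip(w, 0.0, None)) @ v.T
    # BLUPs computed directly as Ĝ Z' V̂⁻¹ (y − Xβ̂); well defined even when
    # the REML fit lands on the boundary (singular Ĝ)
    beta = np.asarray(res.fe_params, dtype=float)
    sigma2 = float(res.scale)
    resid = pc - design.exog @ beta
    blup = {}
    for subj, sl in design.block_slices.items():
        z = design.exog_re[sl]
        v = z @ g @ z.T + sigma2 * np.eye(z.shape[0])
        try:
            blup[subj] = g @ z.T @ np.linalg.solve(v, resid[sl])
        except np.linalg.LinAlgError:  # degenerate fit: V̂ ≈ 0
            blup[subj] = g @ z.T @ (np.linalg.pinv(v) @ resid[sl])
    return PcLmmFit(
        pc_index=r,
        beta_hat=np.asarray(res.fe_params, dtype=float),
        random_cov_hat=g,
        resid_var_hat=float(res.scale),
        blup=blup,
        converged=True,
        method=method,
    )


def marginal_residuals(fit: PcLmmFit, pc: np.ndarray, design: SampleDesign) -> np.ndarray:
    """Population-level residuals e_i = Φ_i − x_i β̂."""
    return np.asarray(pc, dtype=float).ravel() - design.exog @ fit.beta_hat


def conditional_residuals(
    fit: PcLmmFit, pc: np.ndarray, design: SampleDesign
) -> np.ndarray:
    """Subject-level residuals e_i = Φ_i − x_i β̂ − z_i γ̂_i."""
    e = marginal_residuals(fit, pc, design)
    if fit.method == "OLS-fallback":
        warnings.warn(
            "OLS fallback has no BLUPs; conditional residuals equal marginal",
            RuntimeWarning,
            stacklevel=2,
        )
        return e
    out = e.copy()
    for subj, sl in design.block_slices.items():
        out[sl] -= design.exog_re[sl] @ fit.blup[subj]
    return out


def marginal_covariance(fit: PcLmmFit, design: SampleDesign, subject) -> np.ndarray:
    """Estimated marginal covariance V̂_i = Z_i Ĝ Z_i' + σ̂² I of one block."""
    z = design.z_block(subject)
    v = z @ fit.random_cov_hat @ z.T + fit.resid_var_hat * np.eye(z.shape[0])
    v = 0.5 * (v + v.T)
    w = np.linalg.eigvalsh(v)
    if w.min(initial=0.0) < -1e-12 * max(abs(w).max(), 1.0):
        warnings.warn(
            "assembled marginal covariance not PSD; projecting", RuntimeWarning
        )
        wv, vv = np.linalg.eigh(v)
        v = (vv * np.clip(wv, 0.0, None)) @ vv.T
    return v


def _whiten_block(e: np.ndarray, v: np.ndarray) -> np.ndarray:
    m = v.shape[0]
    try:
        L = cholesky(v, lower=True)
    except np.linalg.LinAlgError:
        L = None
    except Exception:
        L = None
    if L is None:
        jitter = 1e-8 * np.trace(v) / m
        warnings.warn(
            f"singular marginal covariance; adding ridge jitter {jitter:.3g}",
            RuntimeWarning,
        )
        try:
            L = cholesky(v + jitter * np.eye(m), lower=True)
        except Exception as err:
            raise np.linalg.LinAlgError(
                "marginal covariance block is singular even after jitter"
            ) from err
    return solve_triangular(L, e, lower=True)


def standardize_residuals(
    resid: np.ndarray, vhats: dict, design: SampleDesign
) -> np.ndarray:
    """Whiten marginal residuals block by block: e*_i = L_i^{-1} e_i with
    V̂_i = L_i L_i'. Blocks follow the design's canonical within-subject order."""
    resid = np.asarray(resid, dtype=float).ravel()
    out = np.empty_like(resid)
    for subj, sl in design.block_slices.items():
        out[sl] = _whiten_block(resid[sl], vhats[subj])
    return out


def _residuals_of_type(
    fit: PcLmmFit, pc: np.ndarray, design: SampleDesign, residual_type: str
) -> np.ndarray:
    if residual_type == "marginal":
        return marginal_residuals(fit, pc, design)
    if residual_type == "conditional":
        return conditional_residuals(fit, pc, design)
    e = marginal_residuals(fit, pc, design)
    vhats = {s: marginal_covariance(fit, design, s) for s in design.block_slices}
    return standardize_residuals(e, vhats, design)


def adjust_pcs_repeated(
    dec: KernelDecomposition,
    design: SampleDesign,
    residual_type: str = "standardized",
) -> ResidualMatrix:
    """Adjust each retained kernel PC with its own LMM and stack the residuals.

    PCs are fitted independently; per-PC convergence diagnostics (estimation
    method, σ̂², random-effect variances) are attached to the result. A PC
    whose fit fails outright is dropped with a warning rather than aborting
    the ordination.
    """
    if residual_type not in RESIDUAL_TYPES:
        raise ValueError(f"residual_type must be one of {RESIDUAL_TYPES}")
    phi = dec.retained_pcs
    if phi.shape[0] != design.n_samples:
        raise ValueError("kernel decomposition and design have different sizes")
    cols, rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(phi.shape[1]):
            pc = phi[:, r]
            try:
                fit = fit_pc_lmm(pc, design)
                fit.pc_index = r
                e = _residuals_of_type(fit, pc, design, residual_type)
            except np.linalg.LinAlgError as err:
                warnings.warn(
                    f"dropping PC {r + 1}: {err}", RuntimeWarning, stacklevel=2
                )
                continue
            cols.append(e)
            diag = {
                "pc": r + 1,
                "method": fit.method,
                "converged": fit.converged,
                "resid_var": fit.resid_var_hat,
            }
            for a, name_a in enumerate(design.exog_re_names):
                diag[f"re_var_{name_a}"] = fit.random_cov_hat[a, a]
            rows.append(diag)
    if not cols:
        raise ValueError("every retained PC failed to fit")
    return ResidualMatrix(
        np.column_stack(cols), residual_type, pd.DataFrame(rows).set_index("pc")
    )


def _projector(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed design is rank deficient")
    q, _ = np.linalg.qr(x)
    return np.eye(x.shape[0]) - q @ q.T


def adjust_kernel_fixed_only(k: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cross-sectional adjustment: project the covariate column space out of
    the kernel, K_adj = (I − P_X) K (I − P_X)."""
    k = np.asarray(k, dtype=float)
    p = _projector(x)
    out = p @ k @ p
    return 0.5 * (out + out.T)


def adjust_kernel_fixed_only_via_pcs(
    dec: KernelDecomposition, x: np.ndarray
) -> np.ndarray:
    """Equivalent residual-matrix route: regress every kernel PC on X by OLS
    and rebuild E E'. Agrees with the projection formula on the PSD part of K."""
    p = _projector(x)
    e = p @ dec.pcs
    return e @ e.T
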