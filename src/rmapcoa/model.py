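"""Model/Results interface for repeated-measures adjusted PCoA.

:class:`RepeatedMeasuresAPCoA` bundles the full pipeline — compositional
transform, ecological distance, Gower centering, kernel PCA, PC retention,
per-PC mixed-model adjustment, kernel reconstruction and re-ordination —
behind a ``fit()`` call returning :class:`APCoAResults`, which carries the
adjusted ordination, the unadjusted decomposition for comparison, per-PC
convergence diagnostics, and plotting/summary helpers.

The cross-sectional fixed-effects-only variant (optionally stratified by
time, as used for baseline comparisons) is exposed as
:func:`run_fixed_only_apcoa`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import (
    AbundanceTable,
    KernelDecomposition,
    aitchison_distance,
    bray_curtis_distance,
    clr_transform,
    gower_center,
    kernel_pcs,
    retain_pcs,
    to_relative_abundance,
)
from .mixed_adjust import (
    RESIDUAL_TYPES,
    SampleDesign,
    adjust_kernel_fixed_only,
    adjust_pcs_repeated,
)
from .ordination import AdjustedOrdination, ordination_frame, pcoa, reconstruct_kernel

__all__ = [
    "WorkflowConfig",
    "RepeatedMeasuresAPCoA",
    "APCoAResults",
    "run_fixed_only_apcoa",
    "build_kernel",
]

KERNELS = ("aitchison", "bray_curtis")
TRANSFORMS = ("clr", "relative", "raw")
_DEFAULT_TRANSFORM = {"aitchison": "clr", "bray_curtis": "relative"}


@dataclass
class WorkflowConfig:
    """End-to-end pipeline settings.

    The CLR transform pairs with the Aitchison kernel (the recommended
    default for compositional counts); Bray-Curtis expects relative
    abundances — CLR output takes negative values and is rejected for it.
    """

    kernel: str = "aitchison"
    transform: Optional[str] = None  # default depends on kernel
    pseudocount: float = 0.5
    retention_threshold: float = 0.9
    fixed_formula: Optional[str] = None
    random_formula: Optional[str] = "1|subject"
    residual_type: str = "standardized"
    time_as_categorical: bool = True
    axes_to_plot: tuple = (1, 2)

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.transform is None:
            self.transform = _DEFAULT_TRANSFORM[self.kernel]
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if self.kernel == "bray_curtis" and self.transform == "clr":
            raise ValueError(
                "CLR-transformed data are not suitable for Bray-Curtis; "
                "use transform='relative'"
            )
        if self.kernel == "aitchison" and self.transform != "clr":
            raise ValueError("the Aitchison kernel requires the CLR transform")
        if not 0 < self.retention_threshold <= 1:
            raise ValueError("retention_threshold must lie in (0, 1]")
        if self.residual_type not in RESIDUAL_TYPES:
            raise ValueError(f"residual_type must be one of {RESIDUAL_TYPES}")

    @property
    def random_spec(self) -> dict:
        """Parse the lme4-style random formula '<terms> | <group>'."""
        if not self.random_formula:
            return {"group": None, "slope": False}
        parts = [s.strip() for s in self.random_formula.split("|")]
        if len(parts) != 2:
            raise ValueError(
                "random formula must look like '1|subject' or '1+time|subject'"
            )
        terms, group = parts
        slope = any(t.strip() not in ("1", "") for t in terms.split("+"))
        return {"group": group, "slope": slope}


def build_kernel(table: AbundanceTable, cfg: WorkflowConfig) -> np.ndarray:
    """Counts -> transform -> distance -> Gower-centered kernel."""
    if cfg.kernel == "aitchison":
        clr = clr_transform(table, cfg.pseudocount)
        dist = aitchison_distance(clr, table.sample_ids)
    else:
        rel = to_relative_abundance(table)
        dist = bray_curtis_distance(rel)
    return gower_center(dist)


class RepeatedMeasuresAPCoA:
    """Adjusted PCoA model for a repeated-measures microbiome study.

    Parameters
    ----------
    table : AbundanceTable
        Samples x taxa counts.
    metadata : DataFrame
        Per-sample covariates, indexed by sample ID (aligned with the table).
    config : WorkflowConfig, optional
        Pipeline settings; keyword arguments override individual fields.

    Examples
    --------
    >>> model = RepeatedMeasuresAPCoA(
    ...     table, metadata,
    ...     fixed_formula="sex + time + sex:time",
    ...     random_formula="1|subject",
    ... )
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(
        self,
        table: AbundanceTable,
        metadata: pd.DataFrame,
        config: Optional[WorkflowConfig] = None,
        time_col: Optional[str] = "time",
        **kwargs,
    ):
        cfg = config or WorkflowConfig()
        if kwargs:
            params = {**cfg.__dict__, **kwargs}
            if "kernel" in kwargs and "transform" not in kwargs:
                params["transform"] = None  # re-derive the kernel's default
            cfg = WorkflowConfig(**params)
        self.config = cfg

        missing = [s for s in table.sample_ids if s not in metadata.index]
        orphans = [s for s in metadata.index if s not in set(table.sample_ids)]
        if missing or orphans:
            raise ValueError(
                f"table/metadata sample IDs misaligned; missing metadata for "
                f"{missing[:5]}, metadata-only samples {orphans[:5]}"
            )
        metadata = metadata.loc[table.sample_ids]
        spec = cfg.random_spec
        time_col = time_col if time_col in metadata.columns else None
        design = SampleDesign(
            metadata,
            subject_col=spec["group"],
            time_col=time_col,
            fixed_formula=cfg.fixed_formula,
            random_slope=spec["slope"],
            time_as_categorical=cfg.time_as_categorical,
        )
        # canonical order: contiguous subject blocks, time-sorted within
        order = design.canonical_order()
        self.design = design.reordered(order)
        self.table = table.select_samples(order)

    @classmethod
    def from_dataframes(
        cls, counts: pd.DataFrame, metadata: pd.DataFrame, **kwargs
    ) -> "RepeatedMeasuresAPCoA":
        return cls(AbundanceTable.from_dataframe(counts), metadata, **kwargs)

    def fit(self) -> "APCoAResults":
        cfg = self.config
        kernel = build_kernel(self.table, cfg)
        dec = retain_pcs(
            kernel_pcs(kernel, self.table.sample_ids), cfg.retention_threshold
        )
        resid = adjust_pcs_repeated(dec, self.design, cfg.residual_type)
        k_star = reconstruct_kernel(resid)
        ordination = pcoa(k_star, self.table.sample_ids)
        return APCoAResults(
            model=self,
            ordination=ordination,
            unadjusted=dec,
            residuals=resid,
            diagnostics=resid.diagnostics,
        )


@dataclass
class APCoAResults:
    """Fitted adjusted ordination with diagnostics.

    Attributes
    ----------
    ordination : AdjustedOrdination
        PCoA of the reconstructed kernel K* = EE'.
    unadjusted : KernelDecomposition
        The pre-adjustment kernel decomposition (for side-by-side plots).
    diagnostics : DataFrame
        Per-PC estimation method, convergence flag and variance components.
    """

    model: RepeatedMeasuresAPCoA
    ordination: AdjustedOrdination
    unadjusted: KernelDecomposition
    residuals: object
    diagnostics: pd.DataFrame

    @property
    def design(self) -> SampleDesign:
        return self.model.design

    def frame(self, axes: Sequence[int] = None) -> pd.DataFrame:
        axes = axes or self.model.config.axes_to_plot
        return ordination_frame(self.ordination, self.design, axes)

    def unadjusted_frame(self, axes: Sequence[int] = None) -> pd.DataFrame:
        axes = axes or self.model.config.axes_to_plot
        dec = self.unadjusted
        lam = dec.eigenvalues[: dec.n_positive]
        ord_ = AdjustedOrdination(
            dec.kernel, dec.pcs, lam, lam / lam.sum(), dec.sample_ids
        )
        return ordination_frame(ord_, self.design, axes)

    def plot(self, color=None, shape=None, facet=None, path=None, axes=None):
        from .plotting import plot_ordination

        return plot_ordination(
            self.frame(axes or self.model.config.axes_to_plot),
            color=color,
            shape=shape,
            facet=facet,
            path=path,
            axes=axes or self.model.config.axes_to_plot,
        )

    def summary(self) -> str:
        cfg = self.model.config
        dec = self.unadjusted
        n_conv = int(self.diagnostics["converged"].sum())
        lines = [
            "Repeated-measures adjusted PCoA",
            "=" * 47,
            f"samples: {self.design.n_samples}   "
            f"subjects/clusters: {len(self.design.subjects)}   "
            f"taxa: {self.model.table.n_taxa}",
            f"kernel: {cfg.kernel} ({cfg.transform} transform, "
            f"pseudocount {cfg.pseudocount})",
            f"fixed effects: {cfg.fixed_formula or '(intercept only)'}",
            f"random effects: {cfg.random_formula or '(none)'}",
            f"residual type: {cfg.residual_type}",
            f"retained PCs: l = {dec.n_retained} of {dec.n_positive} "
            f"({100 * dec.prop_explained:.1f}% of variability)",
            f"LMM fits converged: {n_conv}/{len(self.diagnostics)}",
            "adjusted axes (top 5): "
            + ", ".join(
                f"PC{j + 1} {100 * p:.1f}%"
                for j, p in enumerate(self.ordination.prop_explained[:5])
            ),
        ]
        return "\n".join(lines)


def run_fixed_only_apcoa(
    table: AbundanceTable,
    design: SampleDesign,
    cfg: WorkflowConfig = None,
    stratify_by_time: bool = False,
) -> dict:
    """Cross-sectional fixed-effects-only adjustment (projection formula),
    optionally applied separately within each time stratum.

    Returns a mapping stratum -> AdjustedOrdination (key ``None`` when not
    stratified). A stratum with fewer samples than fixed-effect columns is
    skipped with a warning.
    """
    import warnings

    cfg = cfg or WorkflowConfig()
    if stratify_by_time and design.time_col is None:
        raise ValueError("stratify_by_time requires a time column in the design")
    out = {}
    if not stratify_by_time:
        kernel = build_kernel(table, cfg)
        k_adj = adjust_kernel_fixed_only(kernel, design.exog)
        out[None] = pcoa(k_adj, table.sample_ids)
        return out
    times = design.metadata[design.time_col]
    for t in pd.unique(times):
        idx = np.flatnonzero((times == t).to_numpy())
        sub_design = SampleDesign(
            design.metadata.iloc[idx],
            subject_col=design.subject_col,
            time_col=None,
            fixed_formula=design.fixed_formula,
            time_as_categorical=design.time_as_categorical,
        )
        if len(idx) <= sub_design.exog.shape[1]:
            warnings.warn(
                f"stratum {t!r}: fewer samples than fixed-effect columns; skipped",
                RuntimeWarning,
            )
            continue
        sub_table = table.select_samples(idx)
        kernel = build_kernel(sub_table, cfg)
        k_adj = adjust_kernel_fixed_only(kernel, sub_design.exog)
        out[t] = pcoa(k_adj, sub_table.sample_ids)
    return out
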