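"""Reconstruction of the adjusted kernel and its ordination.

After per-PC adjustment the residual matrix E plays the role of the
square-root factor: K* = E E' is the adjusted kernel (symmetric PSD by
construction). Ordinary PCoA of K* — eigendecomposition with the same
sorting and sign conventions as the forward pass — gives the adjusted
coordinates U*(Λ*)^{1/2}, and each axis carries a fraction λ*_j / Σ λ* of the
residual variability (the trace of K*). Note E itself cannot be plotted
directly: the adjustment reshuffles how much variability each column
explains, so a fresh eigendecomposition is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import kernel_pcs
from .mixed_adjust import ResidualMatrix, SampleDesign

__all__ = ["AdjustedOrdination", "reconstruct_kernel", "pcoa", "ordination_frame"]


@dataclass(frozen=True)
class AdjustedOrdination:
    """Adjusted kernel K*, its coordinates, eigenvalues and per-axis fractions."""

    kernel_adj: np.ndarray
    pcs_adj: np.ndarray  # M x ℓ*, columns U*(Λ*)^{1/2} over positive axes
    eigenvalues_adj: np.ndarray  # positive eigenvalues, nonincreasing
    prop_explained: np.ndarray  # per-axis fraction of residual variability
    sample_ids: list = None

    @property
    def n_axes(self) -> int:
        return self.pcs_adj.shape[1]

    def coordinates(self, axes: Sequence[int]) -> np.ndarray:
        """Columns for 1-based axis indices."""
        axes = [int(a) for a in axes]
        for a in axes:
            if not 1 <= a <= self.n_axes:
                raise ValueError(
                    f"axis {a} out of range (ordination has {self.n_axes} axes)"
                )
        return self.pcs_adj[:, [a - 1 for a in axes]]


def reconstruct_kernel(e: ResidualMatrix | np.ndarray) -> np.ndarray:
    """K* = E E' from the residual matrix; symmetric PSD by construction."""
    values = e.values if isinstance(e, ResidualMatrix) else np.asarray(e, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("residual matrix contains non-finite values")
    if values.ndim == 1:
        values = values[:, None]
    k = values @ values.T
    return 0.5 * (k + k.T)


def pcoa(k_star: np.ndarray, sample_ids: Sequence = None) -> AdjustedOrdination:
    """Principal coordinates of a (reconstructed) kernel.

    Uses the same nonincreasing eigenvalue sort and sign convention as the
    forward kernel decomposition, so a null adjustment round-trips exactly.
    """
    dec = kernel_pcs(k_star, sample_ids)
    lam = dec.eigenvalues[: dec.n_positive]
    total = lam.sum()
    prop = lam / total if total > 0 else np.zeros_like(lam)
    return AdjustedOrdination(
        kernel_adj=dec.kernel,
        pcs_adj=dec.pcs,
        eigenvalues_adj=lam,
        prop_explained=prop,
        sample_ids=dec.sample_ids,
    )


def ordination_frame(
    ord_: AdjustedOrdination, design: SampleDesign, axes: Sequence[int] = (1, 2)
) -> pd.DataFrame:
    """Plot-ready table joining ordination coordinates with sample metadata.

    One row per sample: sample ID, metadata columns, the requested axis
    coordinates (``PC<a>``) and their explained fractions (``prop_PC<a>``).
    """
    coords = ord_.coordinates(axes)
    ids = ord_.sample_ids or design.sample_ids
    if list(ids) != list(design.sample_ids):
        raise ValueError("ordination and design sample IDs do not match")
    out = design.metadata.copy()
    out.insert(0, "sample_id", list(ids))
    for j, a in enumerate(axes):
        out[f"PC{a}"] = coords[:, j]
        out[f"prop_PC{a}"] = float(ord_.prop_explained[a - 1])
    return out.reset_index(drop=True)
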