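"""Compositional transforms, ecological dissimilarities, and kernel principal coordinates.

The entry point of a principal-coordinates analysis is a sample-by-sample
dissimilarity matrix D. Gower double-centering turns the squared
dissimilarities into an inner-product ("kernel") matrix

    K = -1/2 (I - H) (D ∘ D) (I - H),    H = 1 (1'1)^{-1} 1',

whose eigendecomposition K = U Λ U' yields the kernel principal coordinates
Φ = U Λ^{1/2}: rows of Φ embed samples so that their Euclidean distances
approximate (for Euclidean-embeddable D, reproduce) the input dissimilarities.

For compositional microbiome counts the recommended pipeline is the centered
log-ratio (CLR) transform followed by Euclidean distance — the Aitchison
distance — whose Gower kernel is positive semidefinite. Bray-Curtis on
relative abundances is supported as an alternative; its kernel may carry
negative eigenvalues, which are clipped when coordinates are built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AbundanceTable",
    "DistanceMatrix",
    "KernelDecomposition",
    "to_relative_abundance",
    "clr_transform",
    "aitchison_distance",
    "bray_curtis_distance",
    "gower_center",
    "kernel_pcs",
    "retain_pcs",
]

#: relative tolerance used when checking symmetry / centering / PSD-ness
_RTOL = 1e-8


def _as_labels(labels: Sequence, n: int, prefix: str) -> list:
    if labels is None:
        return [f"{prefix}{i}" for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} {prefix} labels, got {len(labels)}")
    if len(set(labels)) != n:
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {prefix} labels: {dupes[:5]}")
    return labels


@dataclass(frozen=True)
class AbundanceTable:
    """Samples-by-taxa abundance matrix with aligned identifiers.

    Parameters
    ----------
    counts : (M, p) array_like
        Nonnegative abundances (raw reads or relative abundances).
    sample_ids, taxon_ids : sequence of hashable, optional
        Unique labels; generated if omitted.
    """

    counts: np.ndarray
    sample_ids: list = None
    taxon_ids: list = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if not np.isfinite(counts).all():
            raise ValueError("counts contain non-finite values")
        if (counts < 0).any():
            raise ValueError("counts contain negative entries")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(
            self, "sample_ids", _as_labels(self.sample_ids, counts.shape[0], "sample")
        )
        object.__setattr__(
            self, "taxon_ids", _as_labels(self.taxon_ids, counts.shape[1], "taxon")
        )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        """Build from a DataFrame with sample IDs in the index, taxa in columns."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, idx) -> "AbundanceTable":
        idx = np.asarray(idx)
        return AbundanceTable(
            self.counts[idx], [self.sample_ids[i] for i in idx], self.taxon_ids
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, hollow, nonnegative matrix of pairwise sample dissimilarities."""

    values: np.ndarray
    metric_name: str = "unknown"
    sample_ids: list = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix contains non-finite values")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > _RTOL * scale:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max() > _RTOL * scale:
            raise ValueError("distance matrix diagonal is not zero")
        if v.min() < -_RTOL * scale:
            raise ValueError("distance matrix has negative entries")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", np.clip(v, 0.0, None))
        object.__setattr__(
            self, "sample_ids", _as_labels(self.sample_ids, v.shape[0], "sample")
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class KernelDecomposition:
    """Gower-centered kernel with its eigensystem and kernel PCs Φ = UΛ^{1/2}.

    ``pcs`` spans every strictly positive eigen-direction; ``n_retained``
    (set by :func:`retain_pcs`) marks how many leading PCs enter the
    downstream mixed-model adjustment, and ``prop_explained`` the cumulative
    eigenvalue fraction they carry.
    """

    kernel: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    pcs: np.ndarray
    sample_ids: list = None
    n_retained: int = None
    prop_explained: float = None
    negative_mass: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self,
            "sample_ids",
            _as_labels(self.sample_ids, self.kernel.shape[0], "sample"),
        )

    @property
    def n_positive(self) -> int:
        return self.pcs.shape[1]

    @property
    def retained_pcs(self) -> np.ndarray:
        """The M x ℓ matrix of retained kernel PCs (requires retain_pcs)."""
        if self.n_retained is None:
            raise ValueError("call retain_pcs() before accessing retained_pcs")
        return self.pcs[:, : self.n_retained]


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample's counts to relative abundances (rows sum to one)."""
    totals = table.counts.sum(axis=1)
    if (totals <= 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"samples with zero total count: {bad}")
    return AbundanceTable(
        table.counts / totals[:, None], table.sample_ids, table.taxon_ids
    )


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of counts, log(x_k) - mean_k log(x_k).

    ``pseudocount`` is added to the raw counts before closure so zero counts
    become finite log-ratios; it may be zero only if the table has no zeros.
    Each output row sums to zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    x = table.counts + pseudocount
    if (x <= 0).any():
        raise ValueError(
            "zero counts present: a positive pseudocount is required for CLR"
        )
    # closure cancels inside the log-ratio, so work on shifted counts directly
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def aitchison_distance(
    clr_matrix: np.ndarray, sample_ids: Sequence = None
) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed compositions."""
    clr_matrix = np.asarray(clr_matrix, dtype=float)
    if not np.isfinite(clr_matrix).all():
        raise ValueError("CLR matrix contains non-finite values")
    d = squareform(pdist(clr_matrix, metric="euclidean"))
    return DistanceMatrix(d, "aitchison", sample_ids)


def bray_curtis_distance(
    relative_table: AbundanceTable | np.ndarray, sample_ids: Sequence = None
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity Σ|u−v| / Σ(u+v) between relative abundances."""
    if isinstance(relative_table, AbundanceTable):
        rel = relative_table.counts
        sample_ids = sample_ids or relative_table.sample_ids
    else:
        rel = np.asarray(relative_table, dtype=float)
    if (rel < 0).any():
        raise ValueError("Bray-Curtis input must be nonnegative")
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(d, "bray_curtis", sample_ids)


def gower_center(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower double-centering: K = -1/2 (I-H)(D∘D)(I-H), H the mean projector.

    Rows and columns of K sum to zero; for Euclidean-embeddable D the result
    is positive semidefinite (Gower's theorem).
    """
    if isinstance(d, DistanceMatrix):
        dv = d.values
    else:
        dv = np.asarray(d, dtype=float)
        scale = max(np.abs(dv).max(), 1.0)
        if dv.ndim != 2 or dv.shape[0] != dv.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.abs(dv - dv.T).max() > _RTOL * scale:
            raise ValueError("distance matrix is not symmetric")
    d2 = dv * dv
    # (I-H) A (I-H) == row/column mean subtraction with the grand mean added back
    row_mean = d2.mean(axis=1, keepdims=True)
    col_mean = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    k = -0.5 * (d2 - row_mean - col_mean + grand)
    return 0.5 * (k + k.T)


def kernel_pcs(k: np.ndarray, sample_ids: Sequence = None) -> KernelDecomposition:
    """Eigendecompose a symmetric kernel and form kernel PCs Φ = UΛ₊^{1/2}.

    Eigenvalues are sorted nonincreasing (stable under ties); eigenvector
    columns are sign-fixed so their largest-magnitude entry is positive.
    Negative eigenvalues (possible for non-Euclidean dissimilarities such as
    Bray-Curtis) are clipped to zero for the PC construction and their mass
    fraction is reported with a warning.
    """
    k = np.asarray(k, dtype=float)
    if not np.isfinite(k).all():
        raise ValueError("kernel contains non-finite entries")
    scale = max(np.abs(k).max(), 1.0)
    if np.abs(k - k.T).max() > _RTOL * scale:
        raise ValueError("kernel is not symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (k + k.T))
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    # reproducible sign convention
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    vecs = vecs * flip
    tol = _RTOL * max(vals.max(initial=0.0), 1.0)
    neg_mass = 0.0
    if vals.min(initial=0.0) < -tol:
        neg_mass = -vals[vals < 0].sum() / max(np.abs(vals).sum(), np.finfo(float).tiny)
        warnings.warn(
            f"kernel has negative eigenvalues (mass fraction {neg_mass:.3g}); "
            "clipping to zero for PC construction",
            RuntimeWarning,
            stacklevel=2,
        )
    pos = np.clip(vals, 0.0, None)
    n_pos = int((pos > tol).sum())
    pcs = vecs[:, :n_pos] * np.sqrt(pos[:n_pos])
    return KernelDecomposition(
        kernel=k,
        eigenvalues=vals,
        eigenvectors=vecs,
        pcs=pcs,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        negative_mass=neg_mass,
    )


def retain_pcs(dec: KernelDecomposition, threshold: float = 0.9) -> KernelDecomposition:
    """Retain the smallest leading set of PCs whose cumulative positive-eigenvalue
    fraction reaches ``threshold`` (dropping low-variance tail PCs stabilises the
    downstream mixed-model fits)."""
    if not 0 < threshold <= 1:
        raise ValueError("retention threshold must lie in (0, 1]")
    pos = dec.eigenvalues[: dec.n_positive]
    frac = np.cumsum(pos) / pos.sum()
    n_keep = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    n_keep = min(n_keep, dec.n_positive)
    return replace(dec, n_retained=n_keep, prop_explained=float(frac[n_keep - 1]))
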