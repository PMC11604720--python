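"""Ordination scatter plots: one facet per time point, aesthetics from metadata."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_ordination"]

_MARKERS = ["o", "^", "s", "D", "v", "P", "X", "*"]


def plot_ordination(
    frame: pd.DataFrame,
    color: str = None,
    shape: str = None,
    facet: str = None,
    axes=(1, 2),
    path=None,
    cmap: str = "tab10",
):
    """Faceted scatter of two ordination axes.

    ``frame`` comes from :func:`rmapcoa.ordination.ordination_frame`; axis
    labels carry the percentage of (residual) variability explained.
    Returns the matplotlib Figure (also written to ``path`` if given).
    """
    xcol, ycol = f"PC{axes[0]}", f"PC{axes[1]}"
    for col in filter(None, (xcol, ycol, color, shape, facet)):
        if col not in frame.columns:
            raise ValueError(f"column '{col}' not present in the ordination frame")

    facets = list(pd.unique(frame[facet])) if facet else [None]
    ncol = len(facets)
    fig, axs = plt.subplots(
        1, ncol, figsize=(4 * ncol, 4), squeeze=False, sharex=True, sharey=True
    )
    colors = list(pd.unique(frame[color])) if color else [None]
    shapes = list(pd.unique(frame[shape])) if shape else [None]
    palette = plt.get_cmap(cmap)

    for k, fval in enumerate(facets):
        ax = axs[0, k]
        sub = frame if fval is None else frame[frame[facet] == fval]
        for ci, cval in enumerate(colors):
            for si, sval in enumerate(shapes):
                pts = sub
                label_parts = []
                if cval is not None:
                    pts = pts[pts[color] == cval]
                    label_parts.append(str(cval))
                if sval is not None:
                    pts = pts[pts[shape] == sval]
                    label_parts.append(str(sval))
                if pts.empty:
                    continue
                ax.scatter(
                    pts[xcol],
                    pts[ycol],
                    c=[palette(ci % 10)],
                    marker=_MARKERS[si % len(_MARKERS)],
                    s=22,
                    alpha=0.8,
                    label=", ".join(label_parts) or None,
                )
        title = f"{facet} = {fval}" if fval is not None else ""
        ax.set_title(title)
        ax.set_xlabel(f"{xcol} ({100 * frame[f'prop_{xcol}'].iloc[0]:.1f}%)")
        if k == 0:
            ax.set_ylabel(f"{ycol} ({100 * frame[f'prop_{ycol}'].iloc[0]:.1f}%)")
    if color or shape:
        handles, labels = axs[0, 0].get_legend_handles_labels()
        if handles:
            fig.legend(handles, labels, loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
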