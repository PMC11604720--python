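"""Quantitative checks on ordinations: group-separation silhouettes.

Visual claims ("groups separate after adjustment") are made measurable with
the silhouette score of a grouping variable computed on two ordination axes,
optionally per stratum (e.g. per time point with coordinates from the joint
embedding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = ["group_silhouette", "stratified_silhouette"]


def group_silhouette(coords: np.ndarray, labels) -> float:
    """Silhouette score of ``labels`` on 2-D (or k-D) coordinates."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two groups for a silhouette score")
    return float(silhouette_score(np.asarray(coords, dtype=float), labels))


def stratified_silhouette(
    coords: np.ndarray, labels, strata, include=None
) -> float:
    """Mean per-stratum silhouette of ``labels`` on shared coordinates.

    ``include`` restricts to the given stratum values (e.g. post-baseline
    time points); strata with a single group level are skipped.
    """
    labels, strata = np.asarray(labels), np.asarray(strata)
    coords = np.asarray(coords, dtype=float)
    values = pd.unique(strata) if include is None else list(include)
    scores = []
    for v in values:
        mask = strata == v
        if len(np.unique(labels[mask])) < 2:
            continue
        scores.append(group_silhouette(coords[mask], labels[mask]))
    if not scores:
        raise ValueError("no stratum had two or more groups")
    return float(np.mean(scores))
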