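"""Intersubject amplitude covariation and hierarchical network clustering.

Networks whose amplitudes rise and fall together across subjects form
functional families (classically one sensory and one cognitive group).
The covariation matrix is the K x K Pearson correlation of the
subjects-by-networks measure matrix; Ward's agglomerative clustering of
that matrix's rows recovers the grouping, and per-subject cluster-mean
amplitudes provide compact summaries for association testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClusterResult",
    "amplitude_covariation",
    "ward_cluster",
    "cluster_amplitude",
]


@dataclass
class ClusterResult:
    covariation: np.ndarray  # (K, K) across-subject correlation
    linkage: np.ndarray  # scipy 4-column merge table
    assignment: np.ndarray  # (K,) cluster ids, 0-based
    n_clusters: int
    dissimilarity: str = "euclidean_rows"
    network_labels: list[str] | None = None

    def __post_init__(self) -> None:
        k = self.covariation.shape[0]
        if self.assignment.shape != (k,):
            raise ValueError("assignment must cover all K networks")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("linkage heights must be non-decreasing")

    @property
    def dendrogram_order(self) -> np.ndarray:
        """Leaf order for a reordered-heatmap display."""
        return np.asarray(hierarchy.leaves_list(self.linkage))

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)


def amplitude_covariation(measure: pd.DataFrame | np.ndarray) -> np.ndarray:
    """K x K Pearson correlation across subjects between network columns."""
    values = (
        measure.to_numpy(dtype=float)
        if isinstance(measure, pd.DataFrame)
        else np.asarray(measure, dtype=float)
    )
    s, k = values.shape
    if s < 3:
        raise ValueError("covariation needs S >= 3 subjects")
    sds = values.std(axis=0)
    if np.any(sds == 0):
        labels = (
            list(measure.columns)
            if isinstance(measure, pd.DataFrame)
            else [f"net{i + 1}" for i in range(k)]
        )
        bad = [labels[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant measure column(s) {bad}: correlation undefined")
    c = np.corrcoef(values, rowvar=False)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


def ward_cluster(
    cov: np.ndarray,
    n_clusters: int = 2,
    dissimilarity: Literal["euclidean_rows", "one_minus_r"] = "euclidean_rows",
    network_labels: list[str] | None = None,
) -> ClusterResult:
    """Ward linkage on the covariation matrix.

    The default treats each network's row of correlations-to-all-networks as
    its feature vector and runs Ward on Euclidean row distances (the standard
    Ward contract); ``one_minus_r`` instead feeds sqrt(2 * (1 - r)) pairwise
    dissimilarities directly.  Ties are broken deterministically by scipy's
    lowest-index merge order.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.shape != (k, k):
        raise ValueError("covariation matrix must be square")
    if not 1 <= n_clusters <= k:
        raise ValueError(f"n_clusters must be in [1, {k}]")
    if dissimilarity == "euclidean_rows":
        dist = pdist(cov, metric="euclidean")
    elif dissimilarity == "one_minus_r":
        d = np.sqrt(np.maximum(2.0 * (1.0 - cov), 0.0))
        np.fill_diagonal(d, 0.0)
        dist = squareform(d, checks=False)
    else:
        raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
    linkage = hierarchy.linkage(dist, method="ward")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust") - 1
    # renumber clusters by first appearance for a stable labelling
    order = {}
    assignment = np.empty(k, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        assignment[i] = order[lab]
    return ClusterResult(
        covariation=cov,
        linkage=linkage,
        assignment=assignment,
        n_clusters=n_clusters,
        dissimilarity=dissimilarity,
        network_labels=network_labels,
    )


def cluster_amplitude(
    measure: pd.DataFrame, cr: ClusterResult
) -> pd.DataFrame:
    """Per-subject unweighted mean of member-network values for each cluster."""
    values = measure.to_numpy(dtype=float)
    if values.shape[1] != cr.assignment.size:
        raise ValueError("measure columns do not match the cluster assignment")
    out = {}
    for cid in range(cr.n_clusters):
        members = cr.members(cid)
        if members.size == 0:
            raise ValueError(f"cluster {cid} is empty")
        out[f"cluster{cid}"] = values[:, members].mean(axis=1)
    df = pd.DataFrame(out, index=measure.index)
    df.attrs["assignment"] = cr.assignment.tolist()
    return df
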