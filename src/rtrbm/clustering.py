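"""Grouping assemblies by temporal-connectivity similarity.

Hidden units whose incoming (rows of Û) or outgoing (columns) temporal
weights look alike are grouped by Ward agglomerative clustering on raw
Euclidean distances, cutting the dendrogram at a distance threshold.  Each
cluster's receptive field is the set of neurons with a strong
visible-to-hidden weight, where "strong" is defined by proportional
thresholding: w_thr is set so that exactly n_strong neurons exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering

__all__ = ["ClusterAssignment", "cluster_U", "receptive_fields", "strong_weight_count"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray           # cluster index per hidden unit
    linkage_heights: np.ndarray  # merge distances of the dendrogram
    threshold: float
    axis: str                    # "rows" (incoming) | "columns" (outgoing)

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).shape[0])


def cluster_U(U_hat: np.ndarray, axis: str = "rows",
              threshold: float = 20.0, zscore: bool = False) -> ClusterAssignment:
    """Ward clustering of Û's incoming rows or outgoing columns.

    Flat clusters are obtained by cutting the linkage tree at ``threshold``
    (Ward/Euclidean distances on raw values by default; ``zscore`` optionally
    standardizes each vector dimension first).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    U_hat = np.asarray(U_hat, dtype=float)
    if U_hat.shape[0] < 2:
        raise ValueError("need at least 2 hidden units to cluster")
    X = U_hat if axis == "rows" else U_hat.T if axis == "columns" else None
    if X is None:
        raise ValueError("axis must be 'rows' or 'columns'")
    if zscore:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    model = AgglomerativeClustering(n_clusters=None, distance_threshold=threshold,
                                    linkage="ward", compute_distances=True)
    labels = model.fit_predict(X)
    return ClusterAssignment(labels=labels, linkage_heights=model.distances_.copy(),
                             threshold=float(threshold), axis=axis)


def receptive_fields(W: np.ndarray, assignment: ClusterAssignment,
                     n_strong: int | None = None):
    """Neuron sets per cluster by proportional weight thresholding.

    ``w_thr`` is set such that exactly ``n_strong`` neurons have
    max_j |W_ji| > w_thr; ties at the threshold admit lower neuron indices
    first until the count is exact.  Each strong neuron joins the cluster of
    its strongest hidden unit.  Default ``n_strong``: 5000, reduced to
    ⌈0.125·Nv⌉ for rasters with fewer than 5000 neurons.

    Returns ``(fields, w_thr)`` with ``fields`` a dict cluster → neuron
    index array.
    """
    W = np.asarray(W, dtype=float)
    nv = W.shape[1]
    if n_strong is None:
        n_strong = 5000 if nv >= 5000 else int(np.ceil(0.125 * nv))
    if n_strong > nv:
        raise ValueError(f"n_strong={n_strong} exceeds {nv} neurons")
    per_neuron_max = np.abs(W).max(axis=0)
    # order by strength descending, lowest index first on ties
    order = np.lexsort((np.arange(nv), -per_neuron_max))
    strong = order[:n_strong]
    w_thr = float(per_neuron_max[strong].min())
    nonzero = per_neuron_max[strong] > 0
    if not np.all(nonzero):
        strong = strong[nonzero]          # fewer neurons with any weight: keep those
    best_unit = np.abs(W[:, strong]).argmax(axis=0)
    fields = {}
    for c in np.unique(assignment.labels):
        members = strong[np.isin(best_unit, np.flatnonzero(assignment.labels == c))]
        fields[int(c)] = np.sort(members)
    return fields, w_thr


def strong_weight_count(W: np.ndarray, multiple_of_sd: float = 0.5) -> np.ndarray:
    """Per-neuron count of weights with |w| > multiple_of_sd · σ(W), where
    σ(W) is the standard deviation over all entries of W.  A cleanly
    'diagonal' assembly decomposition gives every neuron a count of 1."""
    W = np.asarray(W, dtype=float)
    thr = multiple_of_sd * W.std()
    return (np.abs(W) > thr).sum(axis=0)
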