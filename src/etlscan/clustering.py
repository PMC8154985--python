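"""Hierarchical clustering of responsive traces into response motifs.

Agglomerative clustering with Ward's linkage (squared L2 criterion): at
each step the pair of clusters whose merge least increases the total
within-cluster sum of squares is merged. The merge tree is kept so the cut
at k clusters is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core import TraceMatrix

__all__ = ["ClusterResult", "ward_cluster", "cluster_means"]


@dataclass
class ClusterResult:
    """Partition of traces plus the full agglomeration tree.

    ``labels`` are 1..k. ``merge_tree`` is the (n-1, 4) linkage matrix
    (children, height, size); heights are the Ward distances, nondecreasing
    along the agglomeration, and ``delta_sse`` (= height^2 / 2) is the exact
    increase in total within-cluster sum of squares at each merge.
    """

    labels: np.ndarray
    merge_tree: np.ndarray
    k: int
    delta_sse: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merge_tree[:, 2]

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def tree_to_json(self, path) -> None:
        merges = [
            {"children": [int(a), int(b)], "height": float(h), "size": int(s)}
            for a, b, h, s in self.merge_tree
        ]
        with open(path, "w") as f:
            json.dump({"k": self.k, "merges": merges}, f, indent=2)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def ward_cluster(responses, k: int = 4, standardize: bool = True) -> ClusterResult:
    """Cut the Ward agglomeration of the response profiles at ``k`` clusters.

    Rows are z-scored before clustering by default so the partition reflects
    response shape rather than amplitude (``standardize=False`` clusters the
    raw traces). The agglomeration is deterministic given the input order.
    """
    x = responses.data if isinstance(responses, TraceMatrix) else np.asarray(responses, dtype=float)
    if x.ndim != 2:
        raise ValueError("responses must be 2-D (n_traces, n_samples)")
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must lie in [1, {n}]")
    if standardize:
        x = _zscore_rows(x)
    if n == 1:
        return ClusterResult(
            labels=np.array([1]), merge_tree=np.empty((0, 4)), k=1, delta_sse=np.empty(0)
        )
    tree = linkage(x, method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterResult(labels=labels, merge_tree=tree, k=k, delta_sse=tree[:, 2] ** 2 / 2.0)


def cluster_means(result: ClusterResult, traces) -> dict[int, np.ndarray]:
    """Arithmetic mean trace of each cluster, keyed by label."""
    x = traces.data if isinstance(traces, TraceMatrix) else np.asarray(traces, dtype=float)
    if x.shape[0] != result.labels.shape[0]:
        raise ValueError("label count does not match trace count")
    means = {}
    for label in range(1, result.k + 1):
        mask = result.labels == label
        if not mask.any():
            raise ValueError(f"cluster {label} is empty")
        means[label] = x[mask].mean(axis=0)
    return means
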