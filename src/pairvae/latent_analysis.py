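"""Downstream analysis of the cell embedding.

Community clustering on a k-nearest-neighbor graph in latent space, plus
the three evaluation statistics used throughout: adjusted Rand index
against reference partitions, tie-aware Kendall rank correlation for
orderings, and per-group pseudo-bulk Pearson correlation against bulk
reference profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as sk_metrics
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EvalReport",
    "cluster_embedding",
    "adjusted_rand_index",
    "kendall_tau",
    "pseudobulk_correlation",
]


@dataclass
class EvalReport:
    ari: float
    n_clusters_found: int
    kendall_tau: float | None = None
    group_correlations: dict[str, float] | None = None

    def as_dict(self) -> dict:
        out = {"ari": self.ari, "n_clusters_found": self.n_clusters_found}
        if self.kendall_tau is not None:
            out["kendall_tau"] = self.kendall_tau
        if self.group_correlations is not None:
            out["group_correlations"] = self.group_correlations
        return out


def cluster_embedding(Z: np.ndarray, n_neighbors: int = 15, resolution: float = 1.0,
                      seed: int = 0) -> np.ndarray:
    """Leiden community detection on a kNN graph of the embedding.

    Builds a symmetrized k-nearest-neighbor graph on Euclidean distances
    and partitions it with the RB-configuration (modularity with a
    resolution parameter) quality function. Returns 0-based contiguous
    integer labels, deterministic under ``seed``.
    """
    import igraph as ig
    import leidenalg

    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(Z)
    _, idx = nn.kneighbors(Z)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = ig.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel to 0..k-1 in order of first appearance for stable output
    _, first = np.unique(labels, return_index=True)
    remap = {old: new for new, old in enumerate(labels[np.sort(first)])}
    return np.asarray([remap[l] for l in labels], dtype=int)


def adjusted_rand_index(a, b) -> float:
    """Permutation-model-adjusted Rand index between two partitions."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, got {a.shape} vs {b.shape}")
    return float(sk_metrics.adjusted_rand_score(a, b))


def kendall_tau(order_a, order_b) -> float:
    """Tie-aware Kendall tau-b between two orderings."""
    a, b = np.asarray(order_a, dtype=float), np.asarray(order_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"orderings must be 1-D and equal length, got {a.shape} vs {b.shape}")
    tau, _ = stats.kendalltau(a, b, variant="b")
    return float(tau)


def pseudobulk_correlation(X_expr, labels, reference, reference_groups,
                           marker_idx) -> dict[str, float]:
    """Per-group Pearson r between pseudo-bulk means and a bulk reference.

    For each group, cells carrying that label are pooled by taking the
    mean expression over the marker features; the resulting profile is
    correlated with the reference row of the same group restricted to the
    same markers.
    """
    X_expr = np.asarray(X_expr, dtype=float)
    labels = np.asarray(labels)
    reference = np.asarray(reference, dtype=float)
    reference_groups = list(reference_groups)
    marker_idx = np.asarray(marker_idx, dtype=int)
    if labels.shape[0] != X_expr.shape[0]:
        raise ValueError("labels length does not match expression matrix")
    if marker_idx.size and (marker_idx.min() < 0 or marker_idx.max() >= X_expr.shape[1]):
        raise ValueError("marker indices out of range")
    ref_pos = {g: i for i, g in enumerate(reference_groups)}
    out: dict[str, float] = {}
    for group in np.unique(labels):
        if group not in ref_pos:
            raise ValueError(f"group {group!r} missing from reference profiles")
        pooled = X_expr[labels == group][:, marker_idx].mean(axis=0)
        ref = reference[ref_pos[group]][marker_idx]
        r, _ = stats.pearsonr(pooled, ref)
        out[str(group)] = float(r)
    return out
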