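"""Joint hierarchical clustering of genes and accessions on relative expression.

Rows (genes) and columns (accessions) are clustered independently with
agglomerative hierarchical clustering, mirroring how expression heatmaps
stratify both axes; the trees are cut at a user-chosen number of clusters
(never auto-selected). Cluster ids are reassigned by decreasing cluster size
so that "cluster 1" is always the largest, making group references stable
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .errors import GlknetError
from .expression import ExpressionMatrix

_DISTANCES = {"euclidean": "euclidean", "correlation": "correlation"}
_LINKAGES = ("complete", "average", "ward")


@dataclass
class Labeling:
    """item -> cluster id (1..k)."""

    labels: dict
    k: int

    def __post_init__(self):
        bad = {v for v in self.labels.values() if not 1 <= v <= self.k}
        if bad:
            raise GlknetError(f"cluster labels outside 1..{self.k}: {sorted(bad)}")

    def members(self, cluster_id: int):
        return [i for i, c in self.labels.items() if c == cluster_id]

    def sizes(self):
        out = {c: 0 for c in range(1, self.k + 1)}
        for c in self.labels.values():
            out[c] += 1
        return out


# the two axes carry the same structure; distinct aliases keep call sites readable
GeneClustering = Labeling
AccessionGrouping = Labeling


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map raw fcluster ids to 1..k by decreasing size (ties: first occurrence)."""
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_seen[c]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


def _cluster_axis(mat: np.ndarray, names, k: int, distance: str, linkage: str):
    if k > mat.shape[0]:
        raise GlknetError(f"k={k} exceeds number of items ({mat.shape[0]})")
    if k < 2:
        raise GlknetError("k must be >= 2")
    d = pdist(mat, metric=_DISTANCES[distance])
    Z = hierarchy.linkage(d, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_by_size(raw)
    return Labeling(dict(zip(names, (int(v) for v in labels))), k), Z


def hierarchical_bicluster(expr: ExpressionMatrix, k_genes: int, k_accessions: int,
                           distance: str = "euclidean", linkage: str = "complete",
                           return_linkage: bool = False):
    """Cluster genes (rows) and accessions (columns) of a relative expression matrix.

    Defaults (euclidean distance, complete linkage) follow the usual
    expression-heatmap conventions. Returns ``(GeneClustering,
    AccessionGrouping)``; with ``return_linkage`` also the two scipy linkage
    matrices for dendrogram export.
    """
    if expr.scale != "relative":
        raise GlknetError("biclustering expects relative (row-centered) expression")
    if distance not in _DISTANCES:
        raise GlknetError(f"unknown distance {distance!r}")
    if linkage not in _LINKAGES:
        raise GlknetError(f"unknown linkage {linkage!r}")
    if expr.values.isna().any().any():
        raise GlknetError("expression matrix contains missing values")
    mat = expr.values.to_numpy(dtype=float)
    gene_lab, Zg = _cluster_axis(mat, expr.gene_ids, k_genes, distance, linkage)
    acc_lab, Za = _cluster_axis(mat.T, expr.accession_ids, k_accessions, distance, linkage)
    if return_linkage:
        return gene_lab, acc_lab, Zg, Za
    return gene_lab, acc_lab


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two labelings of the same items."""
    a = labels_a.labels if isinstance(labels_a, Labeling) else dict(labels_a)
    b = labels_b.labels if isinstance(labels_b, Labeling) else dict(labels_b)
    if set(a) != set(b):
        raise GlknetError("labelings cover different item sets")
    items = sorted(a)
    return float(adjusted_rand_score([a[i] for i in items], [b[i] for i in items]))


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
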