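"""Branch cutting of average-linkage dendrograms into modules.

Clusters are branches of the dendrogram that coalesce below an absolute
dissimilarity ceiling (default 0.99, the convention for topological-overlap
dissimilarities, where unstructured gene pairs sit at ~1).  A branch whose
root joins two well-separated sub-branches — both at least ``min_size``
genes, with a merge-height gap of at least ``split_gap`` above their own
internal heights — is split recursively, so distinct blocks that happen to
merge below the ceiling are still separated.  Branches smaller than
``min_size`` stay unassigned (-1).

The procedure is fully deterministic: genes are sorted lexicographically
before linkage so that tie-breaking does not depend on input order.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform


def average_linkage(dissim: np.ndarray) -> np.ndarray:
    """Average-linkage dendrogram of a symmetric dissimilarity matrix."""
    d = np.asarray(dissim, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return average(squareform(d, checks=False))


def cut_tree_modules(
    dissim: np.ndarray,
    cut_height: float = 0.99,
    min_size: int = 30,
    split_gap: float = 0.25,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster a dissimilarity matrix; returns int labels, -1 = unassigned.

    `order` optionally gives a permutation applied before linkage (used to
    sort genes lexicographically); labels are returned in the original order.
    """
    n = dissim.shape[0]
    if n == 1:
        return np.array([-1])
    perm = np.arange(n) if order is None else np.asarray(order)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    Z = average_linkage(dissim[np.ix_(perm, perm)])
    root = to_tree(Z)

    # components: maximal branches merging strictly below the ceiling
    components = []

    def collect(node):
        if node.dist < cut_height:
            components.append(node)
        elif not node.is_leaf():
            collect(node.left)
            collect(node.right)

    collect(root)

    clusters = []

    def split(node):
        if node.is_leaf():
            clusters.append(node)
            return
        left, right = node.left, node.right
        gap = node.dist - max(left.dist, right.dist)
        if left.count >= min_size and right.count >= min_size and gap >= split_gap:
            split(left)
            split(right)
        else:
            clusters.append(node)

    for comp in components:
        split(comp)

    labels = np.full(n, -1, dtype=int)
    next_id = 0
    for node in clusters:
        if node.count < min_size:
            continue
        leaves = node.pre_order(lambda leaf: leaf.id)
        labels[perm[leaves]] = next_id
        next_id += 1
    return labels


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 0,1,2,... by decreasing size (-1 preserved)."""
    out = np.full_like(labels, -1)
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    # stable for ties: larger first, then smaller original id
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    for new, i in enumerate(order):
        out[labels == ids[i]] = new
    return out
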