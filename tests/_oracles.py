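"""Independent brute-force reference implementations used as test oracles.

These deliberately share no machinery with the package: neighborhoods come
from a dense O(n²) distance matrix and connected components from
scipy.sparse.csgraph, so agreement with the k-d-tree/union-find production
path is a meaningful check.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

FREE = -1


def brute_neighbor_counts(xy: np.ndarray, eps: float) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 0:
        return np.zeros(0, dtype=int)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    return (d2 <= eps * eps).sum(axis=1)


def brute_dbscan(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Reference DBSCAN labels with the documented conventions.

    Core iff >= min_pts neighbours within eps (self-inclusive, <= compare);
    clusters = connected components of core points, numbered densely by
    first core point in input order; border points take the lowest adjacent
    cluster id; everything else is FREE.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=int)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps * eps
    core = adj.sum(axis=1) >= min_pts

    labels = np.full(n, FREE, dtype=int)
    core_idx = np.flatnonzero(core)
    if core_idx.size:
        sub = adj[np.ix_(core_idx, core_idx)]
        _, comp = connected_components(csr_matrix(sub), directed=False)
        # dense ids in order of first core point
        remap: dict[int, int] = {}
        for pos, i in enumerate(core_idx):
            c = comp[pos]
            if c not in remap:
                remap[c] = len(remap)
            labels[i] = remap[c]
        for i in np.flatnonzero(~core):
            adj_core = core_idx[adj[i, core_idx]]
            if adj_core.size:
                labels[i] = labels[adj_core].min()
    return labels


def partitions_equal(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """True if two labelings induce the same partition (ids may differ);
    FREE must map to FREE."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        return False
    if not np.array_equal(labels_a == FREE, labels_b == FREE):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for a, b in zip(labels_a, labels_b):
        if a == FREE:
            continue
        if mapping.setdefault(a, b) != b or back.setdefault(b, a) != a:
            return False
    return True
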