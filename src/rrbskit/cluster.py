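"""Sample clustering helpers: 1 - Pearson distance, average linkage,
tree-topology comparison and Newick export."""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def correlation_matrix(levels: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of sample level vectors (columns)."""
    if levels.shape[0] < 2:
        raise ValueError("need >= 2 sites to correlate samples")
    sd = levels.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance sample; correlations undefined")
    return np.corrcoef(levels, rowvar=False)


def linkage_from_levels(levels: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering on 1 - Pearson distance."""
    r = correlation_matrix(levels)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def clades(linkage: np.ndarray, labels) -> frozenset:
    """The set of non-trivial clades (leaf-label sets of internal nodes)."""
    n = len(labels)
    members = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for k, (a, b, _d, _c) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        if 1 < len(merged) < n:
            out.add(merged)
    return frozenset(out)


def same_topology(linkage_a, linkage_b, labels) -> bool:
    """Robinson-Foulds distance 0 between the two rooted trees."""
    return clades(linkage_a, labels) == clades(linkage_b, labels)


def cophenetic_correlation(linkage_a, linkage_b) -> float:
    da = hierarchy.cophenet(linkage_a)
    db = hierarchy.cophenet(linkage_b)
    if da.std() == 0 or db.std() == 0:
        return 1.0 if np.allclose(da, db) else 0.0
    return float(np.corrcoef(da, db)[0, 1])


def to_newick(linkage: np.ndarray, labels) -> str:
    tree = hierarchy.to_tree(linkage)

    def fmt(node):
        if node.is_leaf():
            return str(labels[node.id])
        return (
            f"({fmt(node.left)}:{node.dist - node.left.dist:.6g},"
            f"{fmt(node.right)}:{node.dist - node.right.dist:.6g})"
        )

    return fmt(tree) + ";"
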