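"""Internal helpers for working with dendropy trees.

All trees in the package are ``dendropy.Tree`` objects; branch lengths are
in Myr.  These helpers provide root-to-node depths, the Brownian-motion
covariance matrix of a set of tips, and small conveniences shared by the
regression, ancestral-inference and trend-model modules.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .errors import SingularCovarianceError

__all__ = [
    "node_depths",
    "tip_depth_vector",
    "bm_covariance_matrix",
    "mrca_node",
    "is_monophyletic",
    "clone_tree",
    "tree_from_newick_string",
    "topology_hash",
]


def node_depths(tree: dendropy.Tree) -> dict:
    """Map every node to its distance from the start of the root edge.

    A root (seed) edge length, when present, is counted: the depth of the
    root node equals its own edge length.  This makes shared root paths
    contribute to all covariances.
    """
    depths = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        if node.parent_node is None:
            depths[node] = edge
        else:
            depths[node] = depths[node.parent_node] + edge
    return depths


def tip_depth_vector(tree: dendropy.Tree, tips: list[str]) -> np.ndarray:
    depths = node_depths(tree)
    by_label = {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}
    return np.array([by_label[t] for t in tips])


def bm_covariance_matrix(tree: dendropy.Tree, tips: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = depth of the MRCA of tips i, j.

    Diagonal entries are root-to-tip depths.  Raises
    :class:`SingularCovarianceError` if the result is not positive definite
    (e.g. duplicated tips joined by zero-length branches without jitter).
    """
    index = {label: i for i, label in enumerate(tips)}
    if len(index) != len(tips):
        raise SingularCovarianceError("duplicate tip labels in covariance request")
    n = len(tips)
    depths = node_depths(tree)
    C = np.zeros((n, n))
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label if node.taxon else None
            if lbl in index:
                i = index[lbl]
                C[i, i] = depths[node]
                below[node] = [i]
            else:
                below[node] = []
        else:
            groups = [below.pop(ch) for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        C[i, np.asarray(groups[b], dtype=int)] = d
                        C[np.asarray(groups[b], dtype=int), i] = d
            below[node] = [i for g in groups for i in g]
    missing = [t for t in tips if C[index[t], index[t]] == 0.0]
    if missing and not _zero_depth_ok(tree, missing):
        raise SingularCovarianceError(f"tips not found in tree: {missing}")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("BM covariance not positive definite") from exc
    return C


def _zero_depth_ok(tree, labels):
    present = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon}
    return all(t in present for t in labels)


def mrca_node(tree: dendropy.Tree, taxa: set[str]):
    """MRCA node of a set of tip labels, or None if any label is missing."""
    present = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon}
    if not set(taxa) <= present:
        return None
    return tree.mrca(taxon_labels=list(taxa))


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]) -> bool:
    node = mrca_node(tree, taxa)
    if node is None:
        return False
    tips_below = {l.taxon.label for l in node.leaf_iter()}
    return tips_below == set(taxa)


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def tree_from_newick_string(s: str) -> dendropy.Tree:
    from .io import read_newick_string

    return read_newick_string(s)


def topology_hash(tree: dendropy.Tree) -> frozenset:
    """Unrooted-topology fingerprint: the set of non-trivial bipartitions."""
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    parts = set()
    for node in tree.postorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(all_tips) - 1:
            side = min(below, frozenset(all_tips - below), key=sorted)
            parts.add(side)
    return frozenset(parts)
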