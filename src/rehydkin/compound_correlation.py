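"""Hierarchical clustering of treatments by standardised property profiles.

The "compound correlation" analysis groups the 16 (pretreatment ×
drying-temperature) treatments by agglomerative hierarchical clustering
of their z-scored physical/chemical/sensory property vectors, and
represents the result as a dendrogram.  Euclidean distance with Ward
linkage is the default; average and complete linkage are supported.

The feature table is a pandas DataFrame whose index holds the treatment
labels and whose columns hold the property names.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "DendrogramNode",
    "standardize_features",
    "cluster_treatments",
    "cut_tree",
    "export_dendrogram",
    "parse_dendrogram",
]

LINKAGES = ("ward", "average", "complete")


@dataclass(frozen=True)
class DendrogramNode:
    """A node of the binary merge tree.

    Leaves have ``children == ()``, ``height == 0`` and a label; internal
    nodes carry the merge height (cluster distance, standardised units)
    and the set of leaf labels beneath them.
    """

    height: float
    members: frozenset
    children: tuple = ()
    label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


def standardize_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, population SD 1).

    Zero-variance columns carry no clustering information and are dropped
    with a warning.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("feature matrix needs >= 2 rows and >= 1 column")
    values = matrix.astype(float)
    sd = values.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping zero-variance feature column(s): {constant}")
        values = values.drop(columns=constant)
        sd = sd.drop(index=constant)
    if values.shape[1] == 0:
        raise ValueError("all feature columns have zero variance")
    return (values - values.mean(axis=0)) / sd


def cluster_treatments(matrix: pd.DataFrame, distance: str = "euclidean",
                       linkage: str = "ward") -> DendrogramNode:
    """Agglomerate rows of a standardised feature matrix into a merge tree.

    Returns the root DendrogramNode.  Deterministic for a given input:
    distance ties are broken by the smallest row index (scipy's ordering).
    """
    if distance != "euclidean":
        raise ValueError("only euclidean distance is supported")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    labels = [str(lbl) for lbl in matrix.index]
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method=linkage, metric=distance)
    return _tree_from_linkage(Z, labels)


def _tree_from_linkage(Z: np.ndarray, labels: list[str]) -> DendrogramNode:
    n = len(labels)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, members=frozenset([labels[i]]), label=labels[i])
        for i in range(n)
    }
    min_idx = {i: i for i in range(n)}  # child order: smallest original row first
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        if min_idx[a] > min_idx[b]:
            a, b = b, a
        ca, cb = nodes[a], nodes[b]
        nodes[n + i] = DendrogramNode(
            height=float(h), members=ca.members | cb.members, children=(ca, cb)
        )
        min_idx[n + i] = min(min_idx[a], min_idx[b])
    return nodes[n + len(Z) - 1]


def cut_tree(tree: DendrogramNode, fraction_of_root_height: float) -> dict[str, int]:
    """Flat clusters from cutting all merges above ``fraction × root height``.

    Returns a mapping label → cluster id, ids numbered by first appearance
    in a left-to-right traversal.  fraction 1 keeps everything in one
    cluster; fraction 0 makes every leaf its own cluster.
    """
    f = fraction_of_root_height
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction_of_root_height must lie in [0, 1]")
    clusters: list[DendrogramNode] = []

    if f == 0.0:
        def collect(node: DendrogramNode) -> None:
            if node.is_leaf:
                clusters.append(node)
            else:
                for child in node.children:
                    collect(child)
        collect(tree)
    else:
        threshold = f * tree.height

        def collect(node: DendrogramNode) -> None:
            if node.height <= threshold:
                clusters.append(node)
            else:
                for child in node.children:
                    collect(child)
        collect(tree)

    assignment: dict[str, int] = {}
    for cid, node in enumerate(clusters):
        for label in sorted(node.members):
            assignment[label] = cid
    return assignment


_NEEDS_QUOTE = re.compile(r"[\s(),:;\[\]'\"]")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_dendrogram(tree: DendrogramNode) -> str:
    """Serialise a merge tree to Newick with branch lengths = height differences.

    A leaf under a merge at height h gets branch length h; an internal node
    gets its parent's height minus its own.  Labels containing Newick
    metacharacters are single-quoted.
    """

    def render(node: DendrogramNode, parent_height: float) -> str:
        branch = parent_height - node.height
        if node.is_leaf:
            return f"{_format_label(node.label)}:{branch:.12g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{branch:.12g}"

    if tree.is_leaf:
        return f"{_format_label(tree.label)}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def parse_dendrogram(newick: str) -> DendrogramNode:
    """Parse a Newick string produced by :func:`export_dendrogram`.

    Uses scikit-bio's Newick reader, then reconstructs merge heights from
    the branch lengths (leaves sit at height 0).
    """
    from skbio import TreeNode  # deferred: skbio import is slow

    sk = TreeNode.read(io.StringIO(newick), convert_underscores=False)

    def convert(node) -> DendrogramNode:
        if node.is_tip():
            return DendrogramNode(height=0.0, members=frozenset([str(node.name)]),
                                  label=str(node.name))
        children = tuple(convert(c) for c in node.children)
        heights = [c.height + (sk_c.length or 0.0)
                   for c, sk_c in zip(children, node.children)]
        members = frozenset().union(*(c.members for c in children))
        return DendrogramNode(height=float(np.mean(heights)), members=members,
                              children=children)

    return convert(sk)
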