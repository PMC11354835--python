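"""UPGMA clustering of groups from a Mahalanobis distance matrix.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly
merges the closest pair of clusters at height d/2; the distance from the
merged cluster to any other is the size-weighted average of the two
constituent distances, which equals the arithmetic mean of all
between-cluster leaf pairs on the original dissimilarities.  Ties are
broken toward the lexicographically smallest pair of cluster keys so the
merge order is deterministic.  The result is a rooted ultrametric tree,
serializable as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = ["upgma", "UltrametricTree", "TreeNode", "to_newick"]


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; height is the node's distance
    above the leaves (0 for leaves)."""

    name: Optional[str]
    height: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class UltrametricTree:
    """UPGMA tree over group names.

    merges records the history as (key_a, key_b, height) with keys the
    sorted tuples of member leaves; branch lengths are differences of
    heights, so every root-to-leaf path has length root.height.
    """

    root: TreeNode
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    @property
    def height(self) -> float:
        return self.root.height

    def to_newick(self) -> str:
        return to_newick(self)

    def cophenetic(self) -> pd.DataFrame:
        """Cophenetic distances: twice the height of the lowest common
        ancestor for each leaf pair."""
        names = sorted(self.leaf_names)
        idx = {name: i for i, name in enumerate(names)}
        out = np.zeros((len(names), len(names)))

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [visit(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            out[idx[a], idx[b]] = out[idx[b], idx[a]] = 2 * node.height
            return [leaf for grp in groups for leaf in grp]

        visit(self.root)
        return pd.DataFrame(out, index=names, columns=names)

    def is_ultrametric(self, atol: float = 1e-9) -> bool:
        depths: list[float] = []

        def visit(node: TreeNode, above: float) -> None:
            if node.is_leaf:
                depths.append(above + node.height)
            for child in node.children:
                visit(child, above + node.height - child.height)

        visit(self.root, 0.0)
        return bool(np.ptp(depths) <= atol)

    def ascii(self) -> str:
        """Crude text dendrogram for reports."""
        lines: list[str] = []

        def visit(node: TreeNode, prefix: str) -> None:
            if node.is_leaf:
                lines.append(f"{prefix}{node.name}")
                return
            lines.append(f"{prefix}+ h={node.height:.4g}")
            for child in node.children:
                visit(child, prefix + "  ")

        visit(self.root, "")
        return "\n".join(lines)


def _validate_matrix(d: pd.DataFrame) -> pd.DataFrame:
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or arr.shape[0] < 2:
        raise AnalysisError("distance matrix must be square with >= 2 labels")
    if list(d.index) != list(d.columns):
        raise AnalysisError("distance matrix row and column labels differ")
    if np.abs(arr - arr.T).max() > 1e-9:
        raise AnalysisError("distance matrix is not symmetric (tolerance 1e-9)")
    if np.abs(np.diag(arr)).max() > 1e-9:
        raise AnalysisError("distance matrix diagonal must be zero")
    if arr.min() < 0:
        raise AnalysisError("distance matrix has negative entries")
    return d


def upgma(distances: pd.DataFrame) -> UltrametricTree:
    """UPGMA tree from a labelled symmetric distance matrix.

    Merge heights are half the average inter-cluster distance; ties are
    broken toward the lexicographically smallest (key_a, key_b) pair.
    """
    distances = _validate_matrix(distances)
    labels = [str(label) for label in distances.index]
    if len(set(labels)) != len(labels):
        raise AnalysisError("distance matrix labels must be unique")

    # active clusters: key (sorted leaf tuple) -> (node, size)
    clusters: dict[tuple[str, ...], tuple[TreeNode, int]] = {
        (name,): (TreeNode(name=name, height=0.0), 1) for name in labels
    }
    dist: dict[frozenset, float] = {}
    arr = distances.to_numpy(dtype=float)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset([(a,), (labels[j],)])] = arr[i, j]

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best_pair = None
        best_d = np.inf
        for key_a in clusters:
            for key_b in clusters:
                if key_a >= key_b:
                    continue
                d = dist[frozenset([key_a, key_b])]
                if d < best_d - 1e-15 or (
                    abs(d - best_d) <= 1e-15
                    and best_pair is not None
                    and (key_a, key_b) < best_pair
                ):
                    best_d = d
                    best_pair = (key_a, key_b)
        key_a, key_b = best_pair
        node_a, size_a = clusters.pop(key_a)
        node_b, size_b = clusters.pop(key_b)
        height = best_d / 2.0
        new_key = tuple(sorted(key_a + key_b))
        new_node = TreeNode(name=None, height=height, children=[node_a, node_b])
        for other in clusters:
            d_new = (
                size_a * dist.pop(frozenset([key_a, other]))
                + size_b * dist.pop(frozenset([key_b, other]))
            ) / (size_a + size_b)
            dist[frozenset([new_key, other])] = d_new
        dist.pop(frozenset([key_a, key_b]))
        clusters[new_key] = (new_node, size_a + size_b)
        merges.append((key_a, key_b, height))

    root = next(iter(clusters.values()))[0]
    return UltrametricTree(root=root, merges=merges)


def _escape(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: UltrametricTree) -> str:
    """Serialize an ultrametric tree as Newick with branch lengths
    (parseable by standard tree libraries)."""

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_escape(node.name)}:{length:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        if parent_height == node.height:  # root
            return f"({inner})"
        return f"({inner}):{length:.10g}"

    return render(tree.root, tree.root.height) + ";"
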