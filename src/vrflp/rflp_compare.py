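"""Jaccard similarity of binary RFLP profiles and UPGMA clustering.

The similarity between two strains' profiles is ``a / (a + b + c)`` where
``a`` counts features present in both, ``b`` features present only in the
first and ``c`` only in the second.  Distance is ``1 - similarity``.
UPGMA merges the closest pair of clusters, placing the new node at half
the merge distance, with cluster-cluster distance the unweighted
arithmetic mean over member pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import BinaryProfileMatrix


def jaccard(x, y) -> float:
    """Jaccard similarity of two equal-length 0/1 vectors.

    Identical all-zero profiles return 1.0 with a warning (they are
    indistinguishable, not dissimilar).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(
            f"profile length mismatch: {x.shape} vs {y.shape}"
        )
    x = x.astype(bool)
    y = y.astype(bool)
    a = int(np.sum(x & y))
    union = int(np.sum(x | y))
    if union == 0:
        warnings.warn("both profiles are all-zero; similarity set to 1.0",
                      stacklevel=2)
        return 1.0
    return a / union


def pairwise_similarity(matrix: BinaryProfileMatrix) -> pd.DataFrame:
    """Square labeled Jaccard similarity matrix over the profile rows."""
    n = len(matrix.row_labels)
    if n < 2:
        raise ValueError("need at least two profiles")
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = jaccard(matrix.values[i], matrix.values[j])
            values[i, j] = values[j, i] = s
    labels = list(matrix.row_labels)
    return pd.DataFrame(values, index=labels, columns=labels)


def to_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``1 - S``; diagonal forced to exactly zero."""
    dist = 1.0 - similarity
    np.fill_diagonal(dist.values, 0.0)
    return dist


@dataclass(frozen=True)
class Node:
    """A dendrogram node: a leaf (label set) or an internal merge."""

    height: float
    label: str | None = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [leaf for child in self.children for leaf in child.leaves()]


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass(frozen=True)
class Dendrogram:
    """An ultrametric UPGMA tree with merge heights."""

    root: Node

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(self.root.leaves())

    def to_newick(self) -> str:
        def fmt(node: Node, parent_height: float) -> str:
            branch = parent_height - node.height
            length = f":{branch:.10g}"
            if node.is_leaf:
                return _quote(node.label) + length
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}){length}"

        root = self.root
        if root.is_leaf:
            return _quote(root.label) + ";"
        inner = ",".join(fmt(c, root.height) for c in root.children)
        return f"({inner});"

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2x the lowest common merge
        height)."""
        labels = list(self.leaf_labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))

        def visit(node: Node) -> list[str]:
            if node.is_leaf:
                return [node.label]
            child_leaves = [visit(c) for c in node.children]
            for a in range(len(child_leaves)):
                for b in range(a + 1, len(child_leaves)):
                    for la in child_leaves[a]:
                        for lb in child_leaves[b]:
                            d = 2.0 * node.height
                            values[idx[la], idx[lb]] = d
                            values[idx[lb], idx[la]] = d
            return [leaf for part in child_leaves for leaf in part]

        visit(self.root)
        return pd.DataFrame(values, index=labels, columns=labels)

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels from cutting the tree into ``k`` groups (undoing
        the k-1 highest merges; ties on height resolved by merge order)."""
        if not 1 <= k <= len(self.leaf_labels):
            raise ValueError(f"k must be in [1, {len(self.leaf_labels)}]")
        clusters: list[Node] = [self.root]
        while len(clusters) < k:
            top = max(
                (c for c in clusters if not c.is_leaf),
                key=lambda c: c.height,
                default=None,
            )
            if top is None:
                break
            clusters.remove(top)
            clusters.extend(top.children)
        return {
            leaf: ci for ci, node in enumerate(clusters)
            for leaf in node.leaves()
        }


def _validate_distance(dist: pd.DataFrame) -> np.ndarray:
    values = dist.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (values < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return values


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a labeled distance matrix.

    Cluster-cluster distance is the unweighted mean over all member pairs,
    recomputed from the input matrix with a correctly-rounded sum so that
    exact ties stay ties in floating point.  Ties are broken by the
    lexicographically smallest pair of cluster keys, a cluster's key being
    its smallest leaf label, so output is deterministic under row
    permutation.
    """
    import math

    values = _validate_distance(dist)
    labels = [str(lab) for lab in dist.index]
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in distance matrix")

    nodes: dict[int, Node] = {
        i: Node(height=0.0, label=lab) for i, lab in enumerate(labels)
    }
    keys: dict[int, str] = {i: lab for i, lab in enumerate(labels)}
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in nodes}
    next_id = len(labels)

    def mean_linkage(i: int, j: int) -> float:
        mi, mj = members[i], members[j]
        return math.fsum(values[a, b] for a in mi for b in mj) / (
            len(mi) * len(mj)
        )

    while len(nodes) > 1:
        live = sorted(nodes)
        best_pair = None
        best = (np.inf, ("", ""))
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                i, j = live[ai], live[bi]
                dij = mean_linkage(i, j)
                pair_key = tuple(sorted((keys[i], keys[j])))
                if (dij, pair_key) < best:
                    best = (dij, pair_key)
                    best_pair = (i, j)
        i, j = best_pair
        dij = best[0]
        merged = Node(
            height=dij / 2.0,
            children=tuple(
                sorted((nodes[i], nodes[j]),
                       key=lambda c: min(c.leaves()))
            ),
        )
        nodes.pop(i)
        nodes.pop(j)
        nodes[next_id] = merged
        keys[next_id] = min(keys[i], keys[j])
        members[next_id] = members.pop(i) + members.pop(j)
        next_id += 1

    return Dendrogram(root=next(iter(nodes.values())))


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
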