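"""Average-linkage (UPGMA) clustering of run distance matrices.

UPGMA repeatedly merges the pair of clusters with the smallest mean
pairwise distance between their members; the merge height is that mean,
so heights are non-decreasing from the leaves to the root and the tree is
ultrametric. Ties between candidate pairs are broken deterministically by
the lexicographically smallest member labels. The Newick export assigns
each node the branch length ``parent_height/2 - own_height/2`` (leaves sit
at height 0), so the cophenetic distance of two leaves equals the merge
height of their lowest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .matching import DistanceMatrix

__all__ = ["DendrogramNode", "average_linkage_tree", "to_newick",
           "cophenetic_matrix", "leaf_clades"]


@dataclass
class DendrogramNode:
    """A node of a UPGMA dendrogram (leaf or binary merge)."""

    height: float
    label: Optional[str] = None
    children: Tuple["DendrogramNode", ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        """Leaf labels under this node, sorted."""
        if self.is_leaf:
            return [self.label]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return sorted(out)


def average_linkage_tree(d: DistanceMatrix) -> DendrogramNode:
    """UPGMA tree of a symmetric distance matrix (N >= 2)."""
    n = d.n
    if n < 2:
        raise ValueError("need at least two runs to cluster")
    values = d.values
    # active clusters: (node, member indices into the original matrix)
    clusters: List[Tuple[DendrogramNode, np.ndarray]] = [
        (DendrogramNode(0.0, label=lab), np.array([i]))
        for i, lab in enumerate(d.labels)
    ]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia, ib = clusters[a][1], clusters[b][1]
                avg = float(values[np.ix_(ia, ib)].mean())
                tie_key = tuple(sorted((min(clusters[a][0].leaves()),
                                        min(clusters[b][0].leaves()))))
                cand = (avg, tie_key, a, b)
                if best is None or cand < best:
                    best = cand
        avg, _, a, b = best
        node_a, idx_a = clusters[a]
        node_b, idx_b = clusters[b]
        children = tuple(sorted((node_a, node_b),
                                key=lambda nd: min(nd.leaves())))
        merged = DendrogramNode(avg, children=children)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append((merged, np.concatenate([idx_a, idx_b])))
    return clusters[0][0]


def _newick(node: DendrogramNode, parent_height: float) -> str:
    length = parent_height / 2.0 - node.height / 2.0
    if node.is_leaf:
        return f"{node.label}:{length:.10g}"
    inner = ",".join(_newick(c, node.height) for c in node.children)
    return f"({inner}):{length:.10g}"


def to_newick(tree: DendrogramNode) -> str:
    """Newick string with ultrametric branch lengths (leaf depth = root/2)."""
    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(_newick(c, tree.height) for c in tree.children)
    return f"({inner});"


def cophenetic_matrix(tree: DendrogramNode, labels: List[str]) -> np.ndarray:
    """Cophenetic distances (merge height of the LCA) in ``labels`` order."""
    pos = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)))

    def visit(node: DendrogramNode) -> List[str]:
        if node.is_leaf:
            return [node.label]
        sides = [visit(c) for c in node.children]
        for i, left in enumerate(sides):
            for right in sides[i + 1:]:
                for a in left:
                    for b in right:
                        out[pos[a], pos[b]] = out[pos[b], pos[a]] = node.height
        return [lab for side in sides for lab in side]

    visit(tree)
    return out


def leaf_clades(tree: DendrogramNode) -> List[frozenset]:
    """All clades (leaf sets of internal nodes) of the tree."""
    clades: List[frozenset] = []

    def visit(node: DendrogramNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        s = frozenset().union(*(visit(c) for c in node.children))
        clades.append(s)
        return s

    visit(tree)
    return clades
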