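"""Hierarchical trees from distance matrices.

UPGMA (average linkage, ultrametric heights) builds the electrostatic
"epograms"; neighbor-joining builds sequence-divergence trees.  Ties are
broken lexicographically by label pair so trees are reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .epsim import DistanceMatrix

__all__ = [
    "TreeNode",
    "ClusterTree",
    "upgma_tree",
    "nj_tree",
    "cophenetic_matrix",
    "cut_tree",
]


@dataclass
class TreeNode:
    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0   # length of the edge above this node
    height: float = 0.0          # UPGMA merge height (0 at leaves)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_lengths: bool = True) -> str:
        if self.is_leaf:
            s = self.name
        else:
            s = "(" + ",".join(c.newick(with_lengths)
                               for c in self.children) + ")" + self.name
        if with_lengths:
            s += f":{self.branch_length:.6f}"
        return s


@dataclass
class ClusterTree:
    root: TreeNode
    method: str
    labels: list[str]
    merge_order: list[tuple[str, str, float]] = field(default_factory=list)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def to_newick(self, path=None, with_lengths: bool = True) -> str:
        text = self.root.newick(with_lengths).rsplit(":", 1)[0] + ";"
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _validate(d: DistanceMatrix, min_leaves: int) -> np.ndarray:
    m = np.asarray(d.values, dtype=float)
    if np.isnan(m).any():
        raise ValueError("distance matrix contains NaN entries")
    if len(d.labels) < min_leaves:
        raise ValueError(f"need at least {min_leaves} leaves")
    return m.copy()


def upgma_tree(d: DistanceMatrix) -> ClusterTree:
    """Average-linkage agglomeration with ultrametric heights.

    Node heights are half the merge distance; ties break on the
    lexicographically smallest (min-label, max-label) pair.
    """
    m = _validate(d, 2)
    # cluster state: list of (sorted member labels, size, height, node)
    clusters: list[tuple[list[str], int, float, TreeNode]] = [
        ([lab], 1, 0.0, TreeNode(name=lab)) for lab in d.labels]
    merge_order: list[tuple[str, str, float]] = []
    while len(clusters) > 1:
        n = len(clusters)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                key_lab = tuple(sorted((clusters[i][0][0], clusters[j][0][0])))
                cand = (m[i, j], key_lab, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, i, j = best
        li, ni, hi, nodei = clusters[i]
        lj, nj_, hj, nodej = clusters[j]
        height = dist / 2.0
        nodei.branch_length = height - hi
        nodej.branch_length = height - hj
        parent = TreeNode(children=[nodei, nodej], height=height)
        lo, hi = sorted((li[0], lj[0]))
        merge_order.append((lo, hi, float(height)))
        # average-linkage update
        new_row = np.empty(n)
        for k in range(n):
            if k in (i, j):
                continue
            new_row[k] = (ni * m[i, k] + nj_ * m[j, k]) / (ni + nj_)
        keep = [k for k in range(n) if k not in (i, j)]
        m2 = np.zeros((len(keep) + 1, len(keep) + 1))
        m2[:-1, :-1] = m[np.ix_(keep, keep)]
        m2[-1, :-1] = m2[:-1, -1] = new_row[keep]
        m = m2
        clusters = [clusters[k] for k in keep] + [
            (sorted(li + lj), ni + nj_, height, parent)]
    root = clusters[0][3]
    return ClusterTree(root=root, method="upgma", labels=list(d.labels),
                       merge_order=merge_order)


def nj_tree(d: DistanceMatrix) -> ClusterTree:
    """Saitou-Nei neighbor joining; negative branch lengths clamp to 0."""
    m = _validate(d, 2)
    labels = list(d.labels)
    nodes = [TreeNode(name=lab) for lab in labels]
    firsts = [lab for lab in labels]  # tie-break key per active node
    clamped = False

    def clamp(v: float) -> float:
        nonlocal clamped
        if v < 0:
            clamped = True
            return 0.0
        return v

    while len(nodes) > 3:
        n = len(nodes)
        r = m.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * m[i, j] - r[i] - r[j]
                key_lab = tuple(sorted((firsts[i], firsts[j])))
                cand = (q, key_lab, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * m[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = m[i, j] - li
        nodes[i].branch_length = clamp(li)
        nodes[j].branch_length = clamp(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (m[i, :] + m[j, :] - m[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        m2 = np.zeros((len(keep) + 1, len(keep) + 1))
        m2[:-1, :-1] = m[np.ix_(keep, keep)]
        m2[-1, :-1] = m2[:-1, -1] = new_d[keep]
        m = m2
        new_first = min(firsts[i], firsts[j])
        nodes = [nodes[k] for k in keep] + [parent]
        firsts = [firsts[k] for k in keep] + [new_first]

    if len(nodes) == 3:
        # closed-form three-taxon solve
        a = 0.5 * (m[0, 1] + m[0, 2] - m[1, 2])
        b = 0.5 * (m[0, 1] + m[1, 2] - m[0, 2])
        c = 0.5 * (m[0, 2] + m[1, 2] - m[0, 1])
        for node, bl in zip(nodes, (a, b, c)):
            node.branch_length = clamp(bl)
        root = TreeNode(children=nodes)
    elif len(nodes) == 2:
        nodes[0].branch_length = clamp(m[0, 1] / 2.0)
        nodes[1].branch_length = clamp(m[0, 1] / 2.0)
        root = TreeNode(children=nodes)
    else:
        root = nodes[0]
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    return ClusterTree(root=root, method="nj", labels=labels)


def cophenetic_matrix(tree: ClusterTree) -> DistanceMatrix:
    """Pairwise cophenetic distances (2x merge height for UPGMA trees)."""
    labels = tree.leaf_names()
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    m = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.name]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        val = 2.0 * node.height
                        m[idx[a], idx[b]] = m[idx[b], idx[a]] = val
        out: list[str] = []
        for grp in groups:
            out.extend(grp)
        return out

    walk(tree.root)
    return DistanceMatrix(labels, m, {"source": "cophenetic"})


def cut_tree(tree: ClusterTree, height: float) -> dict[str, int]:
    """Flat cluster assignment by cutting a UPGMA tree at a height."""
    if tree.method != "upgma":
        raise ValueError("cut_tree requires an ultrametric (UPGMA) tree")
    assignment: dict[str, int] = {}
    next_id = [0]

    def walk(node: TreeNode) -> None:
        if node.height <= height or node.is_leaf:
            cid = next_id[0]
            next_id[0] += 1
            for leaf in node.leaves():
                assignment[leaf.name] = cid
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return assignment
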