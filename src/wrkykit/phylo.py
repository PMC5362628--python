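"""Distance phylogeny over WRKY domains: p-distance, NJ, bootstrap.

Mirrors the classic MEGA-style defaults for protein NJ trees: pairwise
p-distances with pairwise deletion of gapped columns, Saitou–Nei
neighbor-joining with deterministic tie-breaking, and nonparametric
bootstrap over alignment columns with split-based support.

Group-2 subgroup tags (2a–2e) are assigned by reference clading: the query
takes the tag of the smallest monophyletic reference clade containing it;
when no tag-pure clade exists it falls back to the nearest reference by
p-distance (flagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "ReferencePanel",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
    "assign_subgroup",
]


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


class TreeNode:
    __slots__ = ("label", "children", "parent", "branch_length", "support")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: list = []  # TreeNode
        self.parent: Optional[TreeNode] = None
        self.branch_length: float = 0.0  # length of edge to parent
        self.support: Optional[float] = None

    def add_child(self, child: "TreeNode", length: float) -> None:
        child.parent = self
        child.branch_length = float(length)
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at the final NJ join (trifurcation)."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list:
        return sorted(leaf.label for leaf in self.root.leaves())

    def splits(self) -> set:
        """Nontrivial bipartitions, each as the side without the min label."""
        all_labels = frozenset(self.leaf_labels)
        anchor = min(all_labels)
        out = set()

        def walk(node):
            below = frozenset(l.label for l in node.leaves())
            if node is not self.root and 2 <= len(below) <= len(all_labels) - 2:
                side = all_labels - below if anchor in below else below
                out.add(side)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths realized on the tree."""
        labels = self.leaf_labels
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        m = np.zeros((n, n))

        def below(node) -> dict:
            if node.is_leaf:
                return {node.label: 0.0}
            per_child = []
            for c in node.children:
                d = below(c)
                per_child.append({l: v + c.branch_length for l, v in d.items()})
            for a in range(len(per_child)):
                for b in range(a + 1, len(per_child)):
                    for la, va in per_child[a].items():
                        for lb, vb in per_child[b].items():
                            m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = va + vb
            merged = {}
            for d in per_child:
                merged.update(d)
            return merged

        below(self.root)
        return DistanceMatrix(labels=list(labels), matrix=m)

    def newick(self, decimals: int = 6, with_support: bool = False) -> str:
        def fmt(node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.branch_length:.{decimals}f}"
            kids = sorted(node.children, key=lambda c: min(l.label for l in c.leaves()))
            inner = ",".join(fmt(c) for c in kids)
            label = ""
            if with_support and node.support is not None:
                label = str(int(round(node.support)))
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.branch_length:.{decimals}f}"

        return fmt(self.root) + ";"


@dataclass
class ReferencePanel:
    """Labelled, aligned domain sequences with known subgroup/group tags."""

    sequences: Dict[str, str]
    tags: Dict[str, str]

    def __post_init__(self):
        if set(self.sequences) != set(self.tags):
            raise ValueError("sequence labels and tag labels differ")
        counts: dict = {}
        for tag in self.tags.values():
            counts[tag] = counts.get(tag, 0) + 1
        thin = [t for t, n in counts.items() if n < 2]
        if thin:
            raise ValueError(f"reference panel needs >= 2 sequences per tag; thin: {thin}")


# ---------------------------------------------------------------------------
# distances


def _encode(sequences: Mapping[str, str]):
    labels = list(sequences)
    seqs = [sequences[l] for l in labels]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be aligned to equal length")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return labels, arr.reshape(len(labels), L).copy()


def _pdist_from_array(labels, arr) -> DistanceMatrix:
    gap = arr == ord("-")
    valid = ~gap[:, None, :] & ~gap[None, :, :]
    comparable = valid.sum(axis=2)
    mism = ((arr[:, None, :] != arr[None, :, :]) & valid).sum(axis=2)
    n = len(labels)
    off = ~np.eye(n, dtype=bool)
    if (comparable[off] == 0).any():
        i, j = np.argwhere((comparable == 0) & off)[0]
        raise ValueError(f"no comparable columns for pair ({labels[i]}, {labels[j]})")
    m = np.zeros((n, n))
    m[off] = mism[off] / comparable[off]
    return DistanceMatrix(labels=list(labels), matrix=m)


def p_distance(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise mismatch proportions with pairwise deletion of gap columns."""
    labels, arr = _encode(sequences)
    return _pdist_from_array(labels, arr)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei agglomeration; additive inputs are realized exactly.

    Ties in the Q criterion break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf).  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling edge.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # cluster state: canonical label -> TreeNode; distances in nested dict
    nodes = {}
    dist: dict = {}
    for i, lab in enumerate(dm.labels):
        nodes[lab] = TreeNode(label=lab)
    for i, a in enumerate(dm.labels):
        dist[a] = {}
        for j, b in enumerate(dm.labels):
            if a != b:
                dist[a][b] = float(dm.matrix[i, j])

    def join(a: str, b: str, va: float, vb: float) -> str:
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        va, vb = max(va, 0.0), max(vb, 0.0)
        u = TreeNode()
        u.add_child(nodes[a], va)
        u.add_child(nodes[b], vb)
        lab = min(a, b)
        d_ab = dist[a][b]
        new_d = {}
        for k in dist:
            if k in (a, b):
                continue
            new_d[k] = 0.5 * (dist[a][k] + dist[b][k] - d_ab)
        del dist[a], dist[b], nodes[a], nodes[b]
        for k in list(dist):
            dist[k].pop(a, None)
            dist[k].pop(b, None)
            dist[k][lab] = new_d[k]
        dist[lab] = new_d
        nodes[lab] = u
        return lab

    while len(nodes) > 3:
        labs = sorted(nodes)
        r = len(labs)
        R = {a: sum(dist[a].values()) for a in labs}
        best = None
        for x in range(len(labs)):
            for y in range(x + 1, len(labs)):
                a, b = labs[x], labs[y]
                q = (r - 2) * dist[a][b] - R[a] - R[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        q, a, b = best
        va = 0.5 * dist[a][b] + (R[a] - R[b]) / (2.0 * (r - 2))
        vb = dist[a][b] - va
        join(a, b, va, vb)

    a, b, c = sorted(nodes)
    va = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    vb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    vc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    root = TreeNode()
    for lab, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[lab], max(v, 0.0))
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    sequences: Mapping[str, str], reps: int = 1000, seed: int = 1
) -> PhyloTree:
    """NJ tree with per-split bootstrap support percentages.

    Columns are resampled with replacement; support for each internal
    split of the full-data tree is the percentage of replicate trees
    containing it.  ``reps=0`` returns the plain tree.
    """
    if reps < 0:
        raise ValueError("reps must be >= 0")
    tree = nj_tree(p_distance(sequences))
    if reps == 0:
        return tree
    labels, arr = _encode(sequences)
    L = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict = {s: 0 for s in tree.splits()}
    effective = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        try:
            rep_tree = nj_tree(_pdist_from_array(labels, arr[:, cols]))
        except ValueError:
            continue  # replicate with an incomparable pair
        effective += 1
        rep_splits = rep_tree.splits()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    all_labels = frozenset(tree.leaf_labels)
    anchor = min(all_labels)

    def annotate(node):
        if not node.is_leaf and node is not tree.root:
            below = frozenset(l.label for l in node.leaves())
            if 2 <= len(below) <= len(all_labels) - 2:
                side = all_labels - below if anchor in below else below
                if effective:
                    node.support = 100.0 * counts[side] / effective
        for c in node.children:
            annotate(c)

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# subgroup assignment


def assign_subgroup(
    query_seq: str,
    panel: ReferencePanel,
    query_group: str = "2",
    query_label: str = "__query__",
) -> Tuple[str, str]:
    """Subgroup tag for a group-2 domain by reference clading.

    Returns ``(tag, method)`` with method ``"clade"`` or
    ``"nearest-neighbor fallback"``.
    """
    if str(query_group) != "2":
        raise ValueError("subgroups exist only within group 2")
    if query_label in panel.sequences:
        raise ValueError(f"label {query_label!r} clashes with a panel label")
    seqs = dict(panel.sequences)
    seqs[query_label] = query_seq
    dm = p_distance(seqs)
    tree = nj_tree(dm)
    query_leaf = next(l for l in tree.root.leaves() if l.label == query_label)
    node = query_leaf.parent
    while node is not None:
        ref_leaves = [l.label for l in node.leaves() if l.label != query_label]
        if ref_leaves:
            tags = {panel.tags[l] for l in ref_leaves}
            if len(tags) == 1:
                return tags.pop(), "clade"
        node = node.parent
    # no tag-pure clade anywhere above the query: nearest reference wins
    i = dm.labels.index(query_label)
    best = None
    for j, lab in enumerate(dm.labels):
        if lab == query_label:
            continue
        key = (dm.matrix[i, j], lab)
        if best is None or key < best:
            best = key
    return panel.tags[best[1]], "nearest-neighbor fallback"
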