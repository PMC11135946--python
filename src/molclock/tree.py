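"""Rooted binary trees with node ages.

The central object is :class:`TimeTree`: a rooted, strictly binary,
ultrametric tree whose internal nodes carry ages in Ma (extant tips are
pinned to age 0).  Branch durations are derived, never stored:
``duration(v) = age(parent(v)) - age(v)``.

Nodes are integer ids.  Tips occupy ids ``0 .. n_tips-1`` (in the order
their labels are listed); internal nodes follow.  The same array layout is
reused, without ages, for plain topologies during topology search.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Tree", "TimeTree", "NewickError", "parse_newick", "write_newick"]


class NewickError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate tips, polytomy...)."""


class Tree:
    """Rooted binary topology; branch lengths optional (per-node, to parent).

    Parameters
    ----------
    parent : array of int, ``-1`` for the root.
    children : list of child-id lists (empty for tips).
    labels : tip labels, ``labels[i]`` names node ``i`` for ``i < n_tips``.
    blens : optional per-node branch length to the parent (root entry ignored).
    """

    def __init__(self, parent, children, labels, blens=None):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.blens = None if blens is None else np.asarray(blens, dtype=float)
        if len(set(self.labels)) != self.n_tips:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        for v in range(self.n_nodes):
            nc = len(self.children[v])
            if v < self.n_tips and nc != 0:
                raise ValueError(f"tip node {v} has children")
            if v >= self.n_tips and nc != 2:
                raise NewickError(f"non-binary internal node (id {v}, {nc} children)")
        self._postorder = None
        self._label_to_id = {l: i for i, l in enumerate(self.labels)}

    # -- traversal ---------------------------------------------------------
    @property
    def postorder(self) -> np.ndarray:
        """Node ids, children before parents (cached)."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    @property
    def internal_ids(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    def tip_set(self, v: int) -> frozenset:
        """Labels of tips below (and including) node v."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(self.labels[u])
            stack.extend(self.children[u])
        return frozenset(out)

    def mrca(self, tips) -> int:
        """Most recent common ancestor of a set of tip labels."""
        tips = list(tips)
        if not tips:
            raise ValueError("mrca of empty tip set")
        ids = []
        for l in tips:
            if l not in self._label_to_id:
                raise KeyError(f"unknown tip label: {l!r}")
            ids.append(self._label_to_id[l])
        # path from first tip to root, then ascend the others until they hit it
        path = []
        v = ids[0]
        while v != -1:
            path.append(v)
            v = self.parent[v]
        rank = {v: i for i, v in enumerate(path)}
        best = 0
        for t in ids[1:]:
            v = t
            while v not in rank:
                v = self.parent[v]
            best = max(best, rank[v])
        return path[best]

    def unrooted_splits(self) -> frozenset:
        """Non-trivial bipartitions of the unrooted topology (as tip-label frozensets)."""
        all_tips = frozenset(self.labels)
        splits = set()
        for v in range(self.n_nodes):
            if v == self.root or v < self.n_tips:
                continue
            s = self.tip_set(v)
            if 1 < len(s) < self.n_tips - 1:
                splits.add(min(s, all_tips - s, key=lambda x: tuple(sorted(x))))
        return frozenset(splits)

    def same_unrooted_topology(self, other: "Tree") -> bool:
        return (set(self.labels) == set(other.labels)
                and self.unrooted_splits() == other.unrooted_splits())

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), [list(c) for c in self.children],
                    list(self.labels),
                    None if self.blens is None else self.blens.copy())

    # -- newick ------------------------------------------------------------
    def to_newick(self, lengths: np.ndarray | None = None, digits: int = 10) -> str:
        """Serialize with branch lengths (default: stored blens, if any)."""
        b = lengths if lengths is not None else self.blens

        def rec(v):
            if v < self.n_tips:
                s = self.labels[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if b is not None and v != self.root:
                s += f":{b[v]:.{digits}g}"
            return s

        return rec(self.root) + ";"


class TimeTree(Tree):
    """Rooted binary ultrametric tree with node ages in Ma (tips at 0)."""

    def __init__(self, parent, children, labels, ages):
        super().__init__(parent, children, labels)
        self.ages = np.asarray(ages, dtype=float)
        if np.any(self.ages < 0):
            raise ValueError("negative node age")
        if np.any(self.ages[: self.n_tips] != 0.0):
            raise ValueError("extant tips must have age 0")
        for v in range(self.n_nodes):
            if v != self.root and self.ages[self.parent[v]] <= self.ages[v]:
                raise ValueError(
                    f"age ordering violated at node {v}: parent "
                    f"{self.ages[self.parent[v]]} <= child {self.ages[v]}")

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def durations(self) -> np.ndarray:
        """Per-node branch duration in Ma (root entry = 0)."""
        d = np.zeros(self.n_nodes)
        mask = np.arange(self.n_nodes) != self.root
        d[mask] = self.ages[self.parent[mask]] - self.ages[mask]
        return d

    def to_newick(self, digits: int = 10) -> str:
        return super().to_newick(lengths=self.durations(), digits=digits)

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), [list(c) for c in self.children],
                        list(self.labels), self.ages.copy())

    def with_ages(self, internal_ages: np.ndarray) -> "TimeTree":
        """New TimeTree with internal-node ages replaced (tips stay at 0)."""
        ages = np.zeros(self.n_nodes)
        ages[self.n_tips:] = internal_ages
        return TimeTree(self.parent.copy(), [list(c) for c in self.children],
                        list(self.labels), ages)

    def total_group_node(self, crown: int) -> int:
        """Stem (total-group) node = parent of the crown node."""
        if crown == self.root:
            raise ValueError("total group undefined at root")
        return int(self.parent[crown])


def _from_dendropy(dtree: dendropy.Tree) -> tuple:
    """Flatten a dendropy tree into (parent, children, labels, blens)."""
    nodes = list(dtree.preorder_node_iter())
    tips = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    labels = []
    for n in tips:
        if n.taxon is None or n.taxon.label is None:
            raise NewickError("tip without a label")
        labels.append(str(n.taxon.label).replace(" ", "_"))
    idx = {id(n): i for i, n in enumerate(tips)}
    idx.update({id(n): len(tips) + j for j, n in enumerate(internals)})
    n_nodes = len(nodes)
    parent = np.full(n_nodes, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    blens = np.zeros(n_nodes)
    for n in nodes:
        i = idx[id(n)]
        blens[i] = 0.0 if n.edge.length is None else float(n.edge.length)
        if n.parent_node is not None:
            p = idx[id(n.parent_node)]
            parent[i] = p
            children[p].append(i)
    return parent, children, labels, blens


def parse_topology(text: str) -> Tree:
    """Parse a newick string to a rooted binary :class:`Tree` (lengths kept if present)."""
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {e}") from e
    parent, children, labels, blens = _from_dendropy(dtree)
    return Tree(parent, children, labels, blens)


def parse_newick(text: str, *, ultrametric_tol: float = 1e-6) -> TimeTree:
    """Parse newick with branch lengths into a :class:`TimeTree`.

    Branch lengths are read as durations in Ma; root-to-tip sums must agree
    (ultrametric input) within ``ultrametric_tol`` relative to tree height.
    """
    t = parse_topology(text)
    if t.blens is None:
        raise NewickError("branch lengths required")
    depth = np.zeros(t.n_nodes)
    for v in t.postorder[::-1]:  # preorder
        if v != t.root:
            depth[v] = depth[t.parent[v]] + t.blens[v]
    height = depth[: t.n_tips].max()
    if height <= 0:
        raise NewickError("tree has zero height")
    spread = depth[: t.n_tips].max() - depth[: t.n_tips].min()
    if spread > ultrametric_tol * max(height, 1.0):
        raise NewickError(
            f"input not ultrametric: root-to-tip spans differ by {spread:g}")
    ages = height - depth
    ages[: t.n_tips] = 0.0
    return TimeTree(t.parent, t.children, t.labels, ages)


def write_newick(tree: TimeTree, path=None, digits: int = 10) -> str:
    s = tree.to_newick(digits=digits)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def prune_to(tree: Tree, keep_labels) -> Tree:
    """Restriction of the (unrooted sense) topology to a label subset.

    Degree-2 nodes created by pruning are suppressed; branch lengths, when
    present, are summed across suppressed nodes.
    """
    keep = set(keep_labels)
    missing = keep - set(tree.labels)
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 labels to prune to")
    has_blen = tree.blens is not None

    # recursively rebuild: returns (subtree spec | None)
    def rec(v, acc_len):
        blen = (tree.blens[v] if has_blen else 0.0) + acc_len
        if v < tree.n_tips:
            return ({"label": tree.labels[v], "blen": blen}
                    if tree.labels[v] in keep else None)
        kids = [rec(c, 0.0) for c in tree.children[v]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress degree-2 node
            kids[0]["blen"] += blen
            return kids[0]
        return {"kids": kids, "blen": blen}

    spec = rec(tree.root, 0.0)
    if spec is None or "kids" not in spec:
        raise ValueError("pruned tree has fewer than 2 tips")
    labels = sorted(keep)
    lab_id = {l: i for i, l in enumerate(labels)}
    parent, children, blens = [], [], []
    n_tips = len(labels)
    counter = [n_tips]
    parent_arr = {}
    children_arr = {}
    blen_arr = {}

    def build(node_spec):
        if "label" in node_spec:
            i = lab_id[node_spec["label"]]
        else:
            i = counter[0]
            counter[0] += 1
            children_arr[i] = [build(k) for k in node_spec["kids"]]
        blen_arr[i] = node_spec["blen"]
        return i

    root = build(spec)
    n_nodes = counter[0]
    p = np.full(n_nodes, -1, dtype=int)
    ch = [[] for _ in range(n_nodes)]
    b = np.zeros(n_nodes)
    for i, kids in children_arr.items():
        ch[i] = kids
        for k in kids:
            p[k] = i
    for i, bl in blen_arr.items():
        b[i] = bl
    b[root] = 0.0
    return Tree(p, ch, labels, b if has_blen else None)
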