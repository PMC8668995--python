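"""Distance-based phylogenetics: neighbor joining, midpoint rooting, Newick I/O.

The trees built here stand in for externally computed phylogenies (e.g. a
Bayesian consensus phylogram): neighbor joining on p-distances gives a fast,
deterministic topology, and midpoint rooting places the root halfway along the
longest leaf-to-leaf path, the convention used for unrooted kinase-family
trees. Externally computed trees can be imported as Newick (support values are
kept as internal-node annotations) and compared by Robinson-Foulds distance.

All tie-breaks are lexicographic on leaf labels so identical inputs always
produce identical trees.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class Node:
    """Tree node; ``label`` set on leaves, ``support`` optionally on internals."""

    label: Optional[str] = None
    length: float = 0.0  # branch length to parent; meaningless on the root
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    def add(self, child: "Node", length: float) -> "Node":
        child.parent = self
        child.length = length
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D, labels: Sequence[str]) -> PhyloTree:
    """Standard NJ agglomeration on a symmetric distance matrix.

    The returned tree is unrooted: its root is the final trifurcating node
    (for >3 taxa the last three clusters joined). Q-matrix ties are broken by
    the lexicographically smallest pair of cluster labels, a cluster's label
    being its smallest member leaf. Negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if len(set(labels)) != n:
        raise TreeError("duplicate leaf labels")
    if D.shape != (n, n):
        raise TreeError(f"distance matrix shape {D.shape} does not match {n} labels")
    if np.isnan(D).any():
        raise TreeError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise TreeError("distance matrix is not symmetric")
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")

    nodes = [Node(label=lab) for lab in labels]
    reps = list(labels)  # lexicographic representative per active cluster
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if Q[ai, aj] <= qmin + 1e-12:
                    pair = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                    if best is None or pair < best[0]:
                        best = (pair, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = Node()
        parent.add(nodes[i], li)
        parent.add(nodes[j], lj)

        # distances from the new cluster to the remaining ones
        new_row = np.zeros(D.shape[0])
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    # join the last three clusters on a trifurcating node
    i, j, k = active
    di = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    dj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lens = {i: di, j: dj, k: dk}
    order = sorted(active, key=lambda x: reps[x])
    root = Node()
    for idx in order:
        root.add(nodes[idx], max(lens[idx], 0.0))
    return PhyloTree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: PhyloTree):
    """Undirected graph (node -> list of (neighbor, length)) of the tree."""
    adj: dict[int, list] = {}
    node_of: dict[int, Node] = {}

    def reg(n: Node):
        node_of[id(n)] = n
        adj.setdefault(id(n), [])

    for n in tree.preorder():
        reg(n)
        for c in n.children:
            reg(c)
            adj[id(n)].append((id(c), c.length))
            adj[id(c)].append((id(n), c.length))
    return adj, node_of


def _leaf_paths(adj, node_of, start_id):
    """Distances and predecessor map from one node to all others."""
    dist = {start_id: 0.0}
    prev = {start_id: None}
    stack = [start_id]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                prev[v] = u
                stack.append(v)
    return dist, prev


def tree_diameter_path(tree: PhyloTree):
    """(leaf_a, leaf_b, length, path_node_ids): the longest leaf-to-leaf path.

    Ties are broken by the lexicographically smallest (leaf_a, leaf_b) pair.
    """
    adj, node_of = _adjacency(tree)
    leaves = sorted(tree.leaves(), key=lambda n: n.label)
    best = None
    for la in leaves:
        dist, prev = _leaf_paths(adj, node_of, id(la))
        for lb in leaves:
            if lb.label <= la.label:
                continue
            d = dist[id(lb)]
            key = (-d, la.label, lb.label)
            if best is None or key < best[0]:
                path = []
                cur = id(lb)
                while cur is not None:
                    path.append(cur)
                    cur = prev[cur]
                path.reverse()  # from la to lb
                best = (key, la, lb, d, path)
    _, la, lb, d, path = best
    return la, lb, d, path, adj, node_of


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root. If every branch
    has zero length the midpoint is undefined; the tree is then rooted at its
    basal multifurcation with a warning.
    """
    la, lb, diam, path, adj, node_of = tree_diameter_path(tree)
    if diam <= 0.0:
        warnings.warn("all branch lengths are zero; rooting at the basal node")
        return PhyloTree(root=_rebuild(adj, node_of, id(tree.root), None),
                         rooted=True)
    half = diam / 2.0
    # walk from la toward lb until the midpoint edge
    acc = 0.0
    for a_id, b_id in zip(path, path[1:]):
        w = next(wt for v, wt in adj[a_id] if v == b_id)
        if acc + w >= half - 1e-12:
            da = half - acc  # distance from a_id to the new root
            db = w - da
            root = Node()
            # split edge (a,b): rebuild each side hanging from the new root
            side_a = _rebuild(adj, node_of, a_id, b_id)
            side_b = _rebuild(adj, node_of, b_id, a_id)
            root.add(side_a, max(da, 0.0))
            root.add(side_b, max(db, 0.0))
            _suppress_unary(root)
            return PhyloTree(root=root, rooted=True)
        acc += w
    raise AssertionError("midpoint not found on diameter path")  # pragma: no cover


def _rebuild(adj, node_of, start_id, banned_id) -> Node:
    """Re-orient the subtree reachable from start_id without crossing banned_id."""
    src = node_of[start_id]
    new = Node(label=src.label, support=src.support)
    for v, w in adj[start_id]:
        if v == banned_id:
            continue
        child = _rebuild_rec(adj, node_of, v, start_id)
        new.add(child, w)
    return new


def _suppress_unary(node: Node) -> None:
    """Splice out internal nodes with a single child (old roots after rerooting)."""
    i = 0
    while i < len(node.children):
        child = node.children[i]
        if not child.is_leaf and len(child.children) == 1:
            grand = child.children[0]
            grand.length += child.length
            grand.parent = node
            node.children[i] = grand
            continue  # re-examine: the grandchild might itself be unary
        _suppress_unary(child)
        i += 1


def _rebuild_rec(adj, node_of, cur_id, from_id) -> Node:
    src = node_of[cur_id]
    new = Node(label=src.label, support=src.support)
    for v, w in adj[cur_id]:
        if v == from_id:
            continue
        new.add(_rebuild_rec(adj, node_of, v, cur_id), w)
    return new


def leaf_depths(tree: PhyloTree) -> dict[str, float]:
    """Root-to-leaf path lengths keyed by leaf label."""
    out: dict[str, float] = {}

    def walk(n: Node, depth: float):
        if n.is_leaf:
            out[n.label] = depth
        for c in n.children:
            walk(c, depth + c.length)

    walk(tree.root, 0.0)
    return out


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize to Newick with branch lengths and internal support labels."""

    def fmt(n: Node) -> str:
        if n.is_leaf:
            core = _quote_label(n.label or "")
        else:
            inner = ",".join(fmt(c) for c in n.children)
            sup = ""
            if n.support is not None:
                sup = f"{n.support:g}"
            core = f"({inner}){sup}"
        if n.parent is not None:
            core += f":{round(n.length, precision):g}"
        return core

    return fmt(tree.root) + ";"


def from_newick(text: str) -> PhyloTree:
    """Parse a Newick string (dendropy does the tokenizing).

    Internal node labels that parse as floats become support values.
    Unbalanced parentheses are reported with a character offset; duplicate
    leaf labels are an error.
    """
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeError(f"unbalanced ')' at character {pos}")
    if depth != 0:
        raise TreeError(f"unbalanced '(' ({depth} unclosed) in Newick text")

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            n = Node(label=label)
        else:
            n = Node()
            if dnode.label is not None:
                try:
                    n.support = float(dnode.label)
                except ValueError:
                    n.label = dnode.label
            for dchild in dnode.child_nodes():
                n.add(convert(dchild), float(dchild.edge.length or 0.0))
        return n

    root = convert(dtree.seed_node)
    tree = PhyloTree(root=root, rooted=len(root.children) == 2)
    labels = tree.leaf_labels()
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


# ---------------------------------------------------------------------------
# topology comparison
# ---------------------------------------------------------------------------

def _bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial splits, each canonicalized to the side lacking the smallest leaf."""
    all_leaves = frozenset(tree.leaf_labels())
    smallest = min(all_leaves)
    splits: set[frozenset] = set()

    def walk(n: Node) -> frozenset:
        if n.is_leaf:
            return frozenset([n.label])
        below = frozenset().union(*(walk(c) for c in n.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if smallest not in below else all_leaves - below
            splits.add(side)
        return below

    walk(tree.root)
    return splits


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of nontrivial bipartitions; 0 iff same topology."""
    s1, s2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if s1 != s2:
        only1, only2 = sorted(s1 - s2), sorted(s2 - s1)
        raise TreeError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    return len(_bipartitions(t1) ^ _bipartitions(t2))
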